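import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.special import logsumexp

import memparti as mp
from memparti.pmfkit import MaskedGapError, WindowOverlapError

from conftest import RT298, gaussian_window_sampler


def brute_force_wham(windows, n_bins, z_range, T=298.0):
    """Independent oracle: maximize the WHAM likelihood directly over the
    bin probabilities (softmax-parameterized), not over the window free
    energies as the implementation does."""
    rt = 8.314 * T / 1000.0
    edges = np.linspace(z_range[0], z_range[1], n_bins + 1)
    z = 0.5 * (edges[:-1] + edges[1:])
    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    N = counts.sum(axis=1).astype(float)
    M = counts.sum(axis=0).astype(float)
    pop = M > 0
    logB = -np.stack([w.bias(z[pop]) for w in windows]) / rt

    def nll(theta):
        logp = theta - logsumexp(theta)
        lse_j = logsumexp(logp[None, :] + logB, axis=1)
        val = -float(M[pop] @ logp) + float(N @ lse_j)
        w = np.exp(logp[None, :] + logB - lse_j[:, None])  # (win, bins)
        grad = N @ w - M[pop]
        return val, grad

    res = minimize(nll, np.zeros(pop.sum()), jac=True, method="L-BFGS-B",
                   options={"maxiter": 50000, "ftol": 1e-17, "gtol": 1e-13})
    logp = res.x - logsumexp(res.x)
    dG = np.full(n_bins, np.nan)
    dG[pop] = -rt * logp
    return z, dG


def quadratic_profile(coeff=4.0, z0=1.5, sigma=0.4, n=2001, T=298.15):
    """Analytic Gaussian-well PMF on a fine grid."""
    z = np.linspace(0.0, 4.0, n)
    dG = -coeff * np.exp(-((z - z0) ** 2) / (2 * sigma**2))
    return mp.PMFProfile(z_grid=z, dG=dG, anchor=4.0, temperature=T)


class TestWham:
    def test_flat_underlying_density(self, flat_windows):
        prof = mp.wham(flat_windows, T=298.0)
        ok = np.isfinite(prof.dG)
        inner = ok & (prof.z_grid > 0.2) & (prof.z_grid < 3.8)
        assert np.nanstd(prof.dG[inner]) < 0.5  # kJ/mol

    def test_quadratic_recovery_from_gaussian_oracle_windows(self, quadratic_windows):
        prof = mp.wham(quadratic_windows, T=298.0)
        ok = np.isfinite(prof.dG) & (prof.z_grid < 1.5)
        z, g = prof.z_grid[ok], prof.dG[ok]
        A = np.column_stack([0.5 * z**2, np.ones(z.size)])
        coeff = np.linalg.lstsq(A, g, rcond=None)[0][0]
        assert coeff == pytest.approx(100.0, rel=0.05)

    def test_matches_brute_force_likelihood_oracle(self):
        # 2 windows, 20 samples each: implementation (self-consistent in the
        # window free energies) vs direct likelihood optimization over bin
        # probabilities must agree per populated bin
        rng = np.random.default_rng(11)
        wins = [gaussian_window_sampler(0.0, 0.9, 50.0, 20, rng),
                gaussian_window_sampler(0.0, 1.1, 50.0, 20, rng)]
        prof = mp.wham(wins, n_bins=20, z_range=(0.0, 2.0), T=298.0,
                       tol=1e-13, anchor_width=2.0)
        z, dG = brute_force_wham(wins, 20, (0.0, 2.0))
        ok = np.isfinite(prof.dG)
        impl = prof.dG[ok] - np.mean(prof.dG[ok])
        oracle = dG[ok] - np.mean(dG[ok])
        assert np.max(np.abs(impl - oracle)) < 1e-6

    def test_window_reorder_invariance(self, quadratic_windows):
        a = mp.wham(quadratic_windows, T=298.0)
        b = mp.wham(list(reversed(quadratic_windows)), T=298.0)
        ok = np.isfinite(a.dG)
        assert np.allclose(a.dG[ok], b.dG[ok], atol=1e-6)

    def test_convergence_with_sample_size(self):
        # recovered quadratic coefficient error shrinks as samples grow
        errs = []
        for n in (1000, 10000, 100000):
            rng = np.random.default_rng(5)
            wins = [gaussian_window_sampler(100.0, c, 3000.0, n, rng)
                    for c in np.round(np.arange(0.0, 4.0001, 0.1), 3)]
            prof = mp.wham(wins, T=298.0)
            ok = np.isfinite(prof.dG) & (prof.z_grid < 1.5)
            z, g = prof.z_grid[ok], prof.dG[ok]
            A = np.column_stack([0.5 * z**2, np.ones(z.size)])
            coeff = np.linalg.lstsq(A, g, rcond=None)[0][0]
            errs.append(abs(coeff - 100.0))
        assert errs[2] < errs[0]

    def test_non_overlapping_windows_reported(self):
        rng = np.random.default_rng(1)
        wins = [gaussian_window_sampler(0.0, 0.5, 3000.0, 200, rng),
                gaussian_window_sampler(0.0, 3.5, 3000.0, 200, rng)]
        with pytest.raises(WindowOverlapError, match="0.5"):
            mp.wham(wins)

    def test_needs_two_windows(self, flat_windows):
        with pytest.raises(ValueError):
            mp.wham(flat_windows[:1])


class TestBootstrap:
    def test_duplicated_deterministic_windows_have_zero_error(self):
        z = np.linspace(0.9, 1.3, 500)
        w = mp.UmbrellaWindow(center=1.1, force_const=100.0, samples=z)
        wins = [w, dataclasses.replace(w)]
        prof = mp.bootstrap_pmf(wins, n_boot=8, seed=0,
                                block_length=z.size, n_bins=40,
                                z_range=(0.8, 1.4), anchor_width=0.6)
        ok = np.isfinite(prof.boot_err)
        assert np.all(prof.boot_err[ok] < 1e-12)

    def test_error_grows_as_samples_shrink(self):
        errs = {}
        for n in (1000, 100):
            rng = np.random.default_rng(13)
            wins = [gaussian_window_sampler(0.0, c, 300.0, n, rng)
                    for c in np.arange(0.5, 1.6, 0.1)]
            prof = mp.bootstrap_pmf(wins, n_boot=30, seed=2,
                                    z_range=(0.3, 1.8), n_bins=60,
                                    anchor_width=0.3)
            errs[n] = np.nanmedian(prof.boot_err)
        assert errs[100] > errs[1000]

    def test_requires_windows_and_replicates(self, flat_windows):
        with pytest.raises(ValueError):
            mp.bootstrap_pmf(flat_windows[:1], n_boot=10)
        with pytest.raises(ValueError):
            mp.bootstrap_pmf(flat_windows, n_boot=1)


class TestConvergenceSeries:
    def _windows(self, drift=0.0):
        # stationary (or drifting) Gaussian samples with time stamps
        rng = np.random.default_rng(3)
        wins = []
        for c in np.arange(0.5, 1.6, 0.1):
            n = 2000
            drift_term = drift * np.linspace(0, 1, n)
            s = rng.normal(c, math.sqrt(RT298 / 300.0), n) + drift_term
            wins.append(mp.UmbrellaWindow(center=float(c), force_const=300.0,
                                          samples=s, sample_interval=1.0))
        return wins

    def test_full_range_block_equals_wham(self):
        wins = self._windows()
        kw = dict(z_range=(0.3, 1.8), n_bins=60, anchor_width=0.3, T=298.0)
        full = mp.wham(wins, **kw)
        block = mp.convergence_series(wins, [(0.0, 2000.0)], **kw)[0]
        ok = np.isfinite(full.dG)
        assert np.allclose(full.dG[ok], block.dG[ok], atol=1e-9)

    def test_stationary_blocks_agree(self):
        wins = self._windows()
        kw = dict(z_range=(0.3, 1.8), n_bins=60, anchor_width=0.3, T=298.0)
        boot = mp.bootstrap_pmf(wins, n_boot=30, seed=4, **kw)
        p1, p2 = mp.convergence_series(wins, [(0.0, 1000.0), (1000.0, 2000.0)], **kw)
        ok = np.isfinite(p1.dG) & np.isfinite(p2.dG) & np.isfinite(boot.boot_err)
        # agreement within 2x bootstrap error on the well-populated interior
        inner = ok & (boot.boot_err < 1.0)
        assert np.nanmedian(np.abs(p1.dG[inner] - p2.dG[inner])
                            / np.maximum(2 * boot.boot_err[inner], 1e-3)) < 1.0

    def test_drifting_generator_detected(self):
        wins = self._windows(drift=0.05)
        kw = dict(z_range=(0.3, 1.9), n_bins=60, anchor_width=0.3, T=298.0)
        p1, p2 = mp.convergence_series(wins, [(0.0, 1000.0), (1000.0, 2000.0)], **kw)
        stat1, stat2 = mp.convergence_series(self._windows(),
                                             [(0.0, 1000.0), (1000.0, 2000.0)], **kw)
        ok = (np.isfinite(p1.dG) & np.isfinite(p2.dG)
              & np.isfinite(stat1.dG) & np.isfinite(stat2.dG))
        drift_gap = np.nanmax(np.abs(p1.dG[ok] - p2.dG[ok]))
        stat_gap = np.nanmax(np.abs(stat1.dG[ok] - stat2.dG[ok]))
        assert drift_gap > 2.0 * stat_gap

    def test_empty_block_rejected(self):
        wins = self._windows()
        with pytest.raises(ValueError):
            mp.convergence_series(wins, [(5000.0, 6000.0)])


class TestKpFromPmf:
    def _flat(self, value=0.0, n=401):
        z = np.linspace(0.0, 4.0, n)
        return mp.PMFProfile(z_grid=z, dG=np.full(n, value), anchor=4.0)

    def test_flat_profile_gives_unity(self):
        assert mp.kp_from_pmf(self._flat(), 4.0) == pytest.approx(1.0, rel=1e-12)

    def test_square_well_analytic(self):
        z = np.linspace(0.0, 4.0, 2001)
        rt = 8.314 * 298.15 / 1000.0
        dG = np.where((z >= 1.0) & (z < 1.4), -rt * math.log(10.0), 0.0)
        prof = mp.PMFProfile(z_grid=z, dG=dG, anchor=4.0)
        # (0.4*10 + 3.6)/4 = 1.9
        assert mp.kp_from_pmf(prof, 4.0) == pytest.approx(1.9, rel=2e-3)

    def test_gaussian_well_matches_quadrature(self):
        prof = quadratic_profile()
        rt = 8.314 * prof.temperature / 1000.0
        oracle = quad(lambda zz: math.exp(
            4.0 * math.exp(-((zz - 1.5) ** 2) / (2 * 0.4**2)) / rt),
            0.0, 4.0, limit=400)[0] / 4.0
        assert mp.kp_from_pmf(prof, 4.0) == pytest.approx(oracle, rel=1e-3)

    def test_shift_covariance_exact(self):
        prof = quadratic_profile()
        rt = 8.314 * prof.temperature / 1000.0
        base = mp.kp_from_pmf(prof, 4.0)
        for c in (-3.0, 1.7, 5.0):
            shifted = mp.kp_from_pmf(prof.shifted(c), 4.0)
            assert shifted == pytest.approx(base * math.exp(-c / rt), rel=1e-9)

    def test_masked_gap_rejected(self):
        z = np.linspace(0.0, 4.0, 101)
        dG = np.zeros(101)
        dG[40:45] = np.nan
        prof = mp.PMFProfile(z_grid=z, dG=dG, anchor=4.0)
        with pytest.raises(MaskedGapError):
            mp.kp_from_pmf(prof, 4.0)


class TestDeltaLogKp:
    def test_identical_profiles_zero(self):
        p = quadratic_profile()
        assert mp.delta_log_kp(p, p, 4.0) == pytest.approx(0.0, abs=1e-12)

    def test_five_kj_offset_at_298K(self):
        z = np.linspace(0.0, 4.0, 401)
        A = mp.PMFProfile(z_grid=z, dG=np.zeros(401), anchor=4.0, temperature=298.0)
        B = A.shifted(5.0)
        assert mp.delta_log_kp(A, B, 4.0) == pytest.approx(0.876, abs=1e-3)

    def test_antisymmetry_and_common_shift_invariance(self):
        p1, p2 = quadratic_profile(4.0), quadratic_profile(2.0)
        d = mp.delta_log_kp(p1, p2, 4.0)
        assert mp.delta_log_kp(p2, p1, 4.0) == pytest.approx(-d, abs=1e-12)
        assert mp.delta_log_kp(p1.shifted(3.3), p2.shifted(3.3), 4.0) == \
            pytest.approx(d, abs=1e-9)

    def test_mismatched_temperature_rejected(self):
        p1 = quadratic_profile(T=298.15)
        p2 = quadratic_profile(T=310.0)
        with pytest.raises(ValueError):
            mp.delta_log_kp(p1, p2, 4.0)


class TestSummarizePmf:
    def _profile(self, dG):
        z = np.linspace(0.0, 4.0, dG.size)
        return mp.PMFProfile(z_grid=z, dG=dG, anchor=4.0)

    def test_v_shaped_barrier(self):
        z = np.linspace(0.0, 4.0, 401)
        dG = np.interp(z, [0.0, 0.2, 1.4, 2.5, 4.0], [2.0, 4.0, -20.0, 0.0, 0.0])
        s = mp.summarize_pmf(self._profile(dG))
        assert s.dG_min == pytest.approx(-20.0, abs=0.2)
        assert s.z_max == pytest.approx(0.2, abs=0.02)
        assert s.barrier_from_min == pytest.approx(24.0, abs=0.3)
        assert not s.no_interior_max

    def test_monotone_profile_flagged(self):
        z = np.linspace(0.0, 4.0, 101)
        dG = 10.0 - 2.5 * z  # max at z = 0, no interior maximum
        s = mp.summarize_pmf(self._profile(dG))
        assert s.no_interior_max
        assert s.barrier_from_min == pytest.approx(10.0 - 0.0)
        assert s.dG_max == pytest.approx(s.dG_center)

    def test_flat_profile(self):
        s = mp.summarize_pmf(self._profile(np.zeros(101)))
        assert s.barrier_from_min == 0.0
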