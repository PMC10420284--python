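"""Potentials of mean force from umbrella sampling, and Kp from PMFs.

Umbrella windows restrain the solute at centers z0_j along the bilayer
normal with harmonic biases w_j(z) = 0.5*k_j*(z - z0_j)^2. The unbiased
probability density on a common z grid is recovered with the Weighted
Histogram Analysis Method (WHAM), iterating the self-consistent pair

    P(z)  ∝  sum_j n_j(z)  /  sum_j N_j f_j exp(-w_j(z)/RT)
    f_j^-1 = sum_z P(z) exp(-w_j(z)/RT)

to convergence in max |Δ ln f_j|. The PMF is dG(z) = -RT ln P(z), anchored
to the bulk-water plateau (mean over the outermost stretch of the grid set
to zero). Uncertainty comes from a window-level (plus within-window moving
block) bootstrap; convergence is diagnosed by recomputing the profile on
different time blocks.

A relative partition coefficient follows by Boltzmann-weighting the profile
over the membrane slab, Kp_rel = (1/a) * ∫_0^a exp(-dG(z)/RT) dz. Because
the profile anchor and the slab boundary a are conventions, only ratios
(log10 differences) between profiles computed with a common convention are
meaningful; no absolute Kp is claimed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .constants import (A_BULK_NM, RT_kJ, T_DEFAULT, WHAM_MAX_ITER,
                        WHAM_NBINS, WHAM_TOL)

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "PMFSummary",
    "wham",
    "bootstrap_pmf",
    "convergence_series",
    "kp_from_pmf",
    "delta_log_kp",
    "summarize_pmf",
    "MaskedGapError",
    "WindowOverlapError",
]


class MaskedGapError(ValueError):
    """Unpopulated bins inside the integration range."""


class WindowOverlapError(ValueError):
    """Adjacent umbrella windows share too few populated bins."""


@dataclass(frozen=True)
class UmbrellaWindow:
    """Harmonically biased samples of the reaction coordinate."""

    center: float  # nm
    force_const: float  # kJ mol^-1 nm^-2
    samples: np.ndarray  # z, nm (post-discard)
    sample_interval: float = 1.0  # ps between retained samples
    discarded_time: float = 0.0  # ps dropped from the start of the run

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.force_const <= 0:
            raise ValueError("force_const must be positive")
        if self.samples.size == 0:
            raise ValueError("window has no samples after discard")

    def times(self) -> np.ndarray:
        """Time stamp (ps) of each retained sample."""
        return self.discarded_time + self.sample_interval * np.arange(1, self.samples.size + 1)

    def bias(self, z: np.ndarray) -> np.ndarray:
        """w_j(z), kJ/mol."""
        return 0.5 * self.force_const * (np.asarray(z) - self.center) ** 2


@dataclass(frozen=True)
class PMFProfile:
    """dG(z) on a bin-center grid, anchored so dG(anchor) = 0."""

    z_grid: np.ndarray  # nm, bin centers
    dG: np.ndarray  # kJ/mol, NaN on empty bins
    anchor: float  # nm
    temperature: float = T_DEFAULT
    boot_err: np.ndarray | None = None  # kJ/mol per bin

    def __post_init__(self):
        object.__setattr__(self, "z_grid", np.asarray(self.z_grid, dtype=float))
        object.__setattr__(self, "dG", np.asarray(self.dG, dtype=float))
        if self.boot_err is not None:
            object.__setattr__(self, "boot_err", np.asarray(self.boot_err, dtype=float))

    def shifted(self, c: float) -> "PMFProfile":
        """Profile with a constant c (kJ/mol) added everywhere (anchor moves)."""
        return replace(self, dG=self.dG + c)


@dataclass(frozen=True)
class PMFSummary:
    z_min: float
    dG_min: float
    z_max: float
    dG_max: float
    barrier_from_min: float  # kJ/mol, dG_max - dG_min
    dG_center: float  # value at z = 0
    no_interior_max: bool = False


def _bin_counts(windows, edges):
    """Histogram each window onto the common grid; (n_windows, n_bins)."""
    return np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])


def _check_overlap(windows, counts, min_overlap):
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        shared = np.sum((counts[a] > 0) & (counts[b] > 0))
        if shared < min_overlap:
            raise WindowOverlapError(
                f"windows at centers {windows[a].center:g} and "
                f"{windows[b].center:g} nm share only {shared} populated "
                f"bins (need >= {min_overlap})")


def _anchor_profile(z, dG, anchor_width):
    """Shift so the mean over the outermost anchor_width nm of populated
    bins is zero; returns (dG_shifted, anchor_z)."""
    ok = np.isfinite(dG)
    if not np.any(ok):
        raise ValueError("profile has no populated bins")
    z_hi = z[ok].max()
    sel = ok & (z >= z_hi - anchor_width)
    shift = np.mean(dG[sel])
    return dG - shift, float(z_hi)


def wham(
    windows: Sequence[UmbrellaWindow],
    n_bins: int = WHAM_NBINS,
    z_range: tuple[float, float] = (0.0, A_BULK_NM),
    T: float = T_DEFAULT,
    tol: float = WHAM_TOL,
    max_iter: int = WHAM_MAX_ITER,
    anchor_width: float = 0.5,
    min_overlap: int = 1,
    check_overlap: bool = True,
) -> PMFProfile:
    """Self-consistent WHAM solution on a uniform grid over ``z_range``.

    Raises WindowOverlapError if an adjacent window pair shares fewer than
    ``min_overlap`` populated bins, and RuntimeError at ``max_iter`` without
    max |Δ ln f_j| < tol.
    """
    windows = list(windows)
    if len(windows) < 2:
        raise ValueError("need >= 2 windows")
    if tol <= 0:
        raise ValueError("tol must be positive")
    rt = RT_kJ(T)
    edges = np.linspace(z_range[0], z_range[1], n_bins + 1)
    z = 0.5 * (edges[:-1] + edges[1:])

    counts = _bin_counts(windows, edges)
    if check_overlap:
        _check_overlap(windows, counts, min_overlap)

    N = counts.sum(axis=1).astype(float)  # samples per window inside range
    live = N > 0  # windows with any samples inside the range
    if live.sum() < 2:
        raise ValueError("fewer than 2 windows have samples inside z_range")
    windows_live = [w for w, keep in zip(windows, live) if keep]
    counts = counts[live]
    N = N[live]
    M = counts.sum(axis=0).astype(float)  # total samples per bin
    pop = M > 0
    # log of the bias Boltzmann factors, (n_windows, n_bins)
    logB = -np.stack([w.bias(z) for w in windows_live]) / rt

    logN = np.log(N)
    logM = np.where(pop, np.log(np.where(pop, M, 1.0)), -np.inf)

    def sc_update(g):
        """One self-consistent WHAM update of g_j = ln f_j."""
        denom = logsumexp(logN[:, None] + g[:, None] + logB[:, pop], axis=0)
        logP = logM[pop] - denom
        logP -= logsumexp(logP)
        return -logsumexp(logB[:, pop] + logP, axis=1)

    # The WHAM equations are the stationarity condition of a convex
    # log-likelihood in g; minimize it first (fast), then polish with the
    # self-consistent iteration until the stated tolerance is met.
    Mp = M[pop]

    def nll_and_grad(g):
        lse = logsumexp(logN[:, None] + g[:, None] + logB[:, pop], axis=0,
                        return_sign=False)
        F = float(Mp @ lse - N @ g)
        w = np.exp(logN[:, None] + g[:, None] + logB[:, pop] - lse)
        return F, w @ Mp - N

    res = minimize(nll_and_grad, np.zeros(len(windows_live)), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    g = sc_update(res.x)
    for _ in range(max_iter):
        g_new = sc_update(g)
        if np.max(np.abs(g_new - g)) < tol:
            g = g_new
            break
        g = g_new
    else:
        raise RuntimeError(f"WHAM did not converge in {max_iter} iterations")

    denom = logsumexp(logN[:, None] + g[:, None] + logB, axis=0)
    logP = np.where(pop, logM - denom, -np.inf)
    with np.errstate(invalid="ignore"):
        logP -= logsumexp(logP[pop])
    dG = np.where(pop, -rt * logP, np.nan)
    dG, anchor = _anchor_profile(z, dG, anchor_width)
    return PMFProfile(z_grid=z, dG=dG, anchor=anchor, temperature=T)


def bootstrap_pmf(
    windows: Sequence[UmbrellaWindow],
    n_boot: int = 50,
    seed: int = 0,
    block_length: int | None = None,
    **wham_kwargs,
) -> PMFProfile:
    """WHAM profile with per-bin bootstrap standard deviations.

    Each replicate resamples whole windows with replacement and, within each
    drawn window, moving-block resamples the time series (block length
    defaults to n_samples // 20, floor 1) to respect autocorrelation. Each
    replicate profile is re-anchored before the per-bin SD is taken, so the
    error estimate is invariant to the anchoring convention.
    """
    windows = list(windows)
    if len(windows) < 2:
        raise ValueError("need >= 2 windows")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    base = wham(windows, **wham_kwargs)

    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(windows), size=len(windows))
        drawn = []
        for i in idx:
            w = windows[i]
            n = w.samples.size
            L = block_length or max(n // 20, 1)
            n_blocks = int(np.ceil(n / L))
            starts = rng.integers(0, max(n - L + 1, 1), size=n_blocks)
            resampled = np.concatenate(
                [w.samples[s:s + L] for s in starts])[:n]
            drawn.append(replace(w, samples=resampled))
        try:
            prof = wham(drawn, check_overlap=False, **wham_kwargs)
        except (RuntimeError, ValueError):
            continue  # degenerate resample (coverage gap); skip
        reps.append(prof.dG)
    if len(reps) < 2:
        raise RuntimeError("too few successful bootstrap replicates")
    reps = np.stack(reps)
    ok = np.sum(np.isfinite(reps), axis=0) >= 2
    err = np.full(base.dG.shape, np.nan)
    err[ok] = np.nanstd(reps[:, ok], axis=0, ddof=1)
    return replace(base, boot_err=err)


def convergence_series(
    windows: Sequence[UmbrellaWindow],
    time_blocks: Sequence[tuple[float, float]],
    **wham_kwargs,
) -> list[PMFProfile]:
    """One WHAM profile per time block (t_start, t_end], common binning."""
    profiles = []
    for t0, t1 in time_blocks:
        blocked = []
        for w in windows:
            t = w.times()
            sel = (t > t0) & (t <= t1)
            if not np.any(sel):
                raise ValueError(
                    f"empty block ({t0}, {t1}] for window at {w.center:g} nm")
            blocked.append(replace(w, samples=w.samples[sel]))
        profiles.append(wham(blocked, **wham_kwargs))
    return profiles


def kp_from_pmf(profile: PMFProfile, a: float = A_BULK_NM) -> float:
    """Relative partition coefficient by Boltzmann integration:
    Kp_rel = (1/a) * ∫_0^a exp(-dG(z)/RT) dz, trapezoidal on the bin grid
    extended to the exact [0, a] endpoints.

    Only ratios of values computed with a common anchor and ``a`` are
    meaningful; no absolute Kp is implied.
    """
    rt = RT_kJ(profile.temperature)
    z, dG = profile.z_grid, profile.dG
    inside = (z >= 0.0) & (z <= a)
    if not np.any(inside):
        raise MaskedGapError("profile has no bins inside [0, a]")
    if np.any(~np.isfinite(dG[inside])):
        bad = z[inside][~np.isfinite(dG[inside])]
        raise MaskedGapError(
            f"{bad.size} unpopulated bins inside [0, {a}] nm "
            f"(first at z = {bad[0]:.3f} nm)")
    zi, gi = z[inside], dG[inside]
    grid = np.concatenate(([0.0], zi, [a]))
    vals = np.concatenate(([gi[0]], gi, [gi[-1]]))
    return float(np.trapezoid(np.exp(-vals / rt), grid) / a)


def delta_log_kp(profile_A: PMFProfile, profile_B: PMFProfile,
                 a: float = A_BULK_NM) -> float:
    """log10 Kp_rel(A) - log10 Kp_rel(B) over a common slab [0, a].

    Invariant to any additive constant applied to both profiles.
    """
    if abs(profile_A.temperature - profile_B.temperature) > 1e-9:
        raise ValueError("profiles at different temperatures are not comparable")
    return math.log10(kp_from_pmf(profile_A, a)) - math.log10(kp_from_pmf(profile_B, a))


def summarize_pmf(profile: PMFProfile) -> PMFSummary:
    """Global minimum, the barrier toward the bilayer center, and dG(0).

    The barrier is dG at the highest point on the center side of the global
    minimum (z < z_min) minus dG at the minimum. If the profile is monotone
    (no interior maximum above the end value), the z = 0 value is used and
    the summary is flagged.
    """
    z, dG = profile.z_grid, profile.dG
    ok = np.isfinite(dG)
    if not np.any(ok):
        raise ValueError("empty profile")
    zi, gi = z[ok], dG[ok]
    i_min = int(np.argmin(gi))
    z_min, dG_min = float(zi[i_min]), float(gi[i_min])
    i_center = int(np.argmin(np.abs(zi)))
    dG_center = float(gi[i_center])
    side = gi[: i_min + 1]  # toward z = 0
    i_max = int(np.argmax(side))
    z_max, dG_max = float(zi[i_max]), float(side[i_max])
    no_interior = i_max == i_center or side.size <= 1
    if no_interior:
        z_max, dG_max = float(zi[i_center]), dG_center
    return PMFSummary(z_min=z_min, dG_min=dG_min, z_max=z_max, dG_max=dG_max,
                      barrier_from_min=dG_max - dG_min, dG_center=dG_center,
                      no_interior_max=bool(no_interior))
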