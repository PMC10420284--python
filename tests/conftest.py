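import math

import numpy as np
import pytest

import memparti as mp

RT298 = 8.314 * 298.0 / 1000.0  # kJ/mol


@pytest.fixture(scope="session")
def ph6_truth():
    """Noise-free pH 6 fluorescence world (Kp = 1.8e3, three bands)."""
    return mp.FluorTruth(noise_cv=0.0, seed=0)


@pytest.fixture(scope="session")
def vp_itc_protocol():
    """VP-ITC style uptake protocol: 10 uL x 25 of 10 mM lipid into 5 uM."""
    return mp.ITCProtocol()


def gaussian_window_sampler(G_coeff, center, k, n, rng, T=298.0):
    """Analytic sampler for quadratic G(z) = 0.5*G_coeff*z^2 under a
    harmonic bias 0.5*k*(z-center)^2: the biased density is the Gaussian
    with mean k*center/(k+G_coeff) and variance RT/(k+G_coeff).

    Independent oracle for WHAM tests: no dynamics involved.
    """
    rt = 8.314 * T / 1000.0
    mean = k * center / (k + G_coeff)
    sd = math.sqrt(rt / (k + G_coeff))
    return mp.UmbrellaWindow(center=center, force_const=k,
                             samples=rng.normal(mean, sd, n))


@pytest.fixture(scope="session")
def quadratic_windows():
    """41 analytic-Gaussian windows over [0, 4] nm for G = 0.5*100*z^2."""
    rng = np.random.default_rng(42)
    return [gaussian_window_sampler(100.0, c, 3000.0, 4000, rng)
            for c in np.round(np.arange(0.0, 4.0001, 0.1), 3)]


@pytest.fixture(scope="session")
def flat_windows():
    """Windows sampled from flat G (pure harmonic biases), 41 x 2000."""
    rng = np.random.default_rng(7)
    return [gaussian_window_sampler(0.0, c, 3000.0, 2000, rng)
            for c in np.round(np.arange(0.0, 4.0001, 0.1), 3)]
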