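"""Partition coefficients from fluorescence titrations.

A solute distributed between water and a lipid membrane pseudo-phase
(volume = Vbar * [lipid]) with concentration-ratio partition coefficient Kp
has a bound fraction x/(1+x), x = Kp*Vbar*[L]. Two optical observables
report on that equilibrium:

* fluorescence intensity:  I = (Iw + Im*Kp*Vbar*L) / (1 + Kp*Vbar*L)
* fluorescence anisotropy: r = (rw + aM*rm*Kp*Vbar*L) / (1 + aM*Kp*Vbar*L)

The anisotropy is an intensity-weighted average of the two environments, so
the isotherm is weighted by aM, the ratio of membrane to aqueous emission
intensity in the detection band. aM can be measured from the two endpoint
emission spectra (band-integral ratio) or supplied directly.

Fits are trust-region least squares on (log10 Kp, low endpoint, high
endpoint) with an analytic Jacobian and a 3-decade multistart on Kp;
parameterizing in log10 Kp keeps Kp positive and makes replicate
aggregation (log-normal across titrations) natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import T_DEFAULT, VBAR_POPC

__all__ = [
    "TitrationSeries",
    "PartitionFit",
    "SpectrumPair",
    "titration_model",
    "fit_intensity",
    "fit_anisotropy",
    "joint_band_fit",
    "estimate_alpha_m",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class TitrationSeries:
    """One titration: lipid concentration grid plus one optical signal."""

    lipid: np.ndarray  # mol/L, non-negative ascending
    signal: np.ndarray  # intensity (a.u.) or anisotropy
    kind: str  # "intensity" | "anisotropy"
    band: str = ""  # wavelength-band label, e.g. "450-470"
    pH: float = 7.0
    temperature: float = T_DEFAULT
    lipid_unit: str = "M"

    def __post_init__(self):
        object.__setattr__(self, "lipid", np.asarray(self.lipid, dtype=float))
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if self.kind not in ("intensity", "anisotropy"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.lipid.shape != self.signal.shape:
            raise ValueError("lipid and signal lengths differ")
        if np.any(self.lipid < 0):
            raise ValueError("negative lipid concentration")
        if np.any(np.diff(self.lipid) < 0):
            # store in ascending lipid order; fits are order-invariant
            order = np.argsort(self.lipid, kind="stable")
            object.__setattr__(self, "lipid", self.lipid[order])
            object.__setattr__(self, "signal", self.signal[order])
        if self.kind == "anisotropy" and (
            np.any(self.signal <= -0.2) or np.any(self.signal >= 0.4)
        ):
            raise ValueError("anisotropy values must lie in (-0.2, 0.4)")


@dataclass(frozen=True)
class PartitionFit:
    """Result of a partition isotherm fit."""

    Kp: float
    endpoint_low: float  # Iw or rw
    endpoint_high: float  # Im or rm
    alphaM: float  # weighting actually used (1 for intensity)
    stderr: dict = field(default_factory=dict)  # per-parameter asymptotic SE
    residual_norm: float = 0.0
    n_points: int = 0
    identifiable: bool = True
    message: str = ""

    @property
    def log10_Kp(self) -> float:
        return math.log10(self.Kp)


@dataclass(frozen=True)
class SpectrumPair:
    """Endpoint emission spectra of the probe in water and in the membrane."""

    wavelengths: np.ndarray  # nm, ascending
    I_water: np.ndarray  # a.u.
    I_membrane: np.ndarray  # a.u.

    def __post_init__(self):
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, float))
        object.__setattr__(self, "I_water", np.asarray(self.I_water, float))
        object.__setattr__(self, "I_membrane", np.asarray(self.I_membrane, float))
        if not (self.wavelengths.shape == self.I_water.shape == self.I_membrane.shape):
            raise ValueError("spectra must share one wavelength grid")
        if np.any(self.I_water < 0) or np.any(self.I_membrane < 0):
            raise ValueError("spectra must be non-negative")


def titration_model(
    lipid: np.ndarray,
    Kp: float,
    low: float,
    high: float,
    alphaM: float = 1.0,
    Vbar: float = VBAR_POPC,
    gamma: float = 1.0,
) -> np.ndarray:
    """Forward partition isotherm shared by Eq.-2-style intensity and
    Eq.-3-style anisotropy curves.

    ``gamma`` is the accessible-lipid fraction (1 = all lipid accessible,
    i.e. full translocation during equilibration).
    """
    u = alphaM * Kp * Vbar * gamma * np.asarray(lipid, dtype=float)
    return (low + high * u) / (1.0 + u)


def _residual_and_jac(theta, lipid, signal, alphaM, Vbar, gamma, weights):
    log10Kp, low, high = theta
    u = alphaM * (10.0**log10Kp) * Vbar * gamma * lipid
    denom = 1.0 + u
    model = (low + high * u) / denom
    r = (model - signal) * weights
    J = np.empty((lipid.size, 3))
    J[:, 0] = (high - low) * u * _LN10 / denom**2 * weights
    J[:, 1] = weights / denom
    J[:, 2] = u / denom * weights
    return r, J


def _single_series_fit(
    series: TitrationSeries,
    alphaM: float,
    Vbar: float,
    gamma: float,
    weights: np.ndarray | None,
) -> PartitionFit:
    lipid, signal = series.lipid, series.signal
    n = lipid.size
    if n < 3 or np.unique(lipid).size < 3:
        raise ValueError("need >= 3 distinct lipid concentrations")
    w = np.ones(n) if weights is None else np.asarray(weights, float)

    scale = max(np.max(np.abs(signal)), 1.0)
    if np.ptp(signal) <= 1e-12 * scale:
        return PartitionFit(
            Kp=1.0, endpoint_low=float(signal[0]), endpoint_high=float(signal[0]),
            alphaM=alphaM, stderr={}, residual_norm=0.0, n_points=n,
            identifiable=False, message="flat signal: Kp unconstrained",
        )

    low0, high0 = float(signal[0]), float(signal[-1])
    # half-saturation heuristic: lipid where the signal crosses its midpoint
    mid = 0.5 * (low0 + high0)
    pos = lipid[lipid > 0]
    cross = lipid[np.argmin(np.abs(signal - mid))]
    if cross <= 0:
        cross = float(np.median(pos)) if pos.size else 1e-3
    guess = math.log10(1.0 / (alphaM * Vbar * gamma * cross))

    best = None
    for start in (guess - 1.0, guess, guess + 1.0):
        try:
            res = least_squares(
                lambda th: _residual_and_jac(th, lipid, signal, alphaM, Vbar, gamma, w)[0],
                x0=[start, low0, high0],
                jac=lambda th: _residual_and_jac(th, lipid, signal, alphaM, Vbar, gamma, w)[1],
                method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise RuntimeError("partition fit did not converge (all multistarts failed)")

    log10Kp, low, high = best.x
    _, J = _residual_and_jac(best.x, lipid, signal, alphaM, Vbar, gamma, w)
    stderr, identifiable, msg = _asymptotic_stderr(J, best.fun, n)
    Kp = 10.0**log10Kp
    se = {}
    if identifiable:
        se = {
            "log10_Kp": stderr[0],
            "Kp": Kp * _LN10 * stderr[0],
            "endpoint_low": stderr[1],
            "endpoint_high": stderr[2],
        }
    if abs(high - low) <= 1e-9 * scale:
        identifiable, msg = False, "endpoints coincide: signal carries no Kp information"
    return PartitionFit(
        Kp=Kp, endpoint_low=float(low), endpoint_high=float(high), alphaM=alphaM,
        stderr=se, residual_norm=float(np.linalg.norm(best.fun)), n_points=n,
        identifiable=identifiable, message=msg,
    )


def _asymptotic_stderr(J, residuals, n):
    p = J.shape[1]
    dof = max(n - p, 1)
    s2 = float(residuals @ residuals) / dof
    U, sv, _ = np.linalg.svd(J, full_matrices=False)
    if sv[0] <= 0 or sv[-1] / sv[0] < 1e-10:
        return None, False, "singular Jacobian: parameters not jointly identifiable"
    cov = np.linalg.inv(J.T @ J) * s2
    return np.sqrt(np.diag(cov)), True, ""


def fit_intensity(
    series: TitrationSeries,
    Vbar: float = VBAR_POPC,
    gamma: float = 1.0,
    weights: np.ndarray | None = None,
) -> PartitionFit:
    """Fit (Iw, Im, Kp) to an intensity titration.

    Requires >= 4 distinct lipid concentrations, ideally including a
    zero-lipid (free solute) anchor.
    """
    if series.kind != "intensity":
        raise ValueError("fit_intensity requires an intensity series")
    return _single_series_fit(series, 1.0, Vbar, gamma, weights)


def fit_anisotropy(
    series: TitrationSeries,
    alphaM: float,
    Vbar: float = VBAR_POPC,
    gamma: float = 1.0,
    weights: np.ndarray | None = None,
) -> PartitionFit:
    """Fit (rw, rm, Kp) to an anisotropy titration with fixed aM weighting."""
    if series.kind != "anisotropy":
        raise ValueError("fit_anisotropy requires an anisotropy series")
    if alphaM <= 0:
        raise ValueError("alphaM must be positive")
    return _single_series_fit(series, alphaM, Vbar, gamma, weights)


def estimate_alpha_m(spectra: SpectrumPair, band: tuple[float, float]) -> float:
    """aM = band integral of the membrane spectrum over that of the water
    spectrum (trapezoidal), with the band edges interpolated onto the grid."""
    lo, hi = float(band[0]), float(band[1])
    wl = spectra.wavelengths
    if lo >= hi:
        raise ValueError("band must be an increasing (lo, hi) interval")
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(f"band ({lo}, {hi}) nm outside spectral grid "
                         f"[{wl[0]}, {wl[-1]}] nm")
    inner = wl[(wl > lo) & (wl < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    Iw = np.interp(grid, wl, spectra.I_water)
    Im = np.interp(grid, wl, spectra.I_membrane)
    denom = np.trapezoid(Iw, grid)
    if denom <= 0:
        raise ValueError("water spectrum integrates to zero in the band")
    return float(np.trapezoid(Im, grid) / denom)


def joint_band_fit(
    series_list: Sequence[TitrationSeries],
    alphaM_list: Sequence[float],
    Vbar: float = VBAR_POPC,
    gamma: float = 1.0,
) -> PartitionFit:
    """Fit one shared Kp across several bands/series, each with its own aM
    weighting and its own pair of signal endpoints.

    Returns a PartitionFit whose endpoints are those of the first series;
    per-series endpoints are reported in ``stderr['endpoints']``.
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("empty series list")
    if len(alphaM_list) != len(series_list):
        raise ValueError("need one alphaM per series")
    units = {s.lipid_unit for s in series_list}
    if len(units) > 1:
        raise ValueError(f"inconsistent lipid units across series: {sorted(units)}")

    # parameters: log10Kp, then (low, high) per series
    def unpack(theta):
        return theta[0], theta[1:].reshape(-1, 2)

    def resid(theta):
        lk, ends = unpack(theta)
        out = []
        for s, aM, (lo, hi) in zip(series_list, alphaM_list, ends):
            u = aM * (10.0**lk) * Vbar * gamma * s.lipid
            out.append((lo + hi * u) / (1.0 + u) - s.signal)
        return np.concatenate(out)

    # seed shared Kp with the median of per-series fits
    per = []
    for s, aM in zip(series_list, alphaM_list):
        f = _single_series_fit(s, aM, Vbar, gamma, None)
        per.append(f)
    lk0 = float(np.median([math.log10(f.Kp) for f in per if f.identifiable] or [3.0]))
    theta0 = np.concatenate([[lk0]] + [[f.endpoint_low, f.endpoint_high] for f in per])
    res = least_squares(resid, theta0, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not res.success:
        raise RuntimeError("joint band fit did not converge")
    lk, ends = unpack(res.x)
    n = sum(s.lipid.size for s in series_list)
    return PartitionFit(
        Kp=10.0**lk, endpoint_low=float(ends[0, 0]), endpoint_high=float(ends[0, 1]),
        alphaM=float(alphaM_list[0]),
        stderr={"endpoints": ends.tolist()},
        residual_norm=float(np.linalg.norm(res.fun)), n_points=n,
    )
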