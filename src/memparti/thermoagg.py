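"""Thermodynamic bookkeeping for membrane partition.

Interconverts the partition coefficient Kp with the standard free energy of
partition (dG = -RT ln Kp, with the membrane pseudo-phase volume defined by
the lipid molar volume Vbar), splits dG into enthalpic and entropic terms
(dG = dH - TdS), and aggregates replicate Kp determinations in log10 space —
log Kp, not Kp, is the normally distributed variable across replicate
titrations, so means and standard deviations are formed on log10 Kp and the
representative Kp is the geometric mean 10**mu_log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import R, T_DEFAULT

__all__ = [
    "ThermoRecord",
    "LogKpSummary",
    "dG_from_kp",
    "kp_from_dG",
    "tds_from",
    "summarize_log_kp",
]


@dataclass(frozen=True)
class ThermoRecord:
    """Consistent (Kp, dG, dH, TdS) quadruple at temperature T.

    Energies in kJ/mol. ``dG = dH - TdS`` and ``dG = -RT ln Kp`` must hold
    to 1e-9 kJ/mol; violations raise at construction.
    """

    Kp: float
    dG: float
    dH: float
    TdS: float
    T: float = T_DEFAULT

    def __post_init__(self):
        if abs(self.dG - (self.dH - self.TdS)) > 1e-9:
            raise ValueError("dG != dH - TdS")
        if abs(self.dG - dG_from_kp(self.Kp, self.T)) > 1e-9:
            raise ValueError("dG inconsistent with -RT ln Kp")

    @classmethod
    def from_kp_dh(cls, Kp: float, dH: float, T: float = T_DEFAULT) -> "ThermoRecord":
        dG = dG_from_kp(Kp, T)
        return cls(Kp=Kp, dG=dG, dH=dH, TdS=tds_from(dH, dG), T=T)


@dataclass(frozen=True)
class LogKpSummary:
    """Replicate aggregation of partition coefficients in log10 space."""

    n: int
    mu_log: float
    sigma_log: float
    Kp_mu: float

    def rounded(self) -> dict:
        """Display rounding: 1 decimal in log10, 2 s.f. in Kp.

        Internal values stay unrounded; Kp_mu here is recomputed from the
        unrounded mean, matching tables whose Kp cells reflect unrounded
        log means.
        """
        return {
            "n": self.n,
            "mu_log": round(self.mu_log, 1),
            "sigma_log": round(self.sigma_log, 2),
            "Kp_mu": float(f"{self.Kp_mu:.1e}"),
        }


def dG_from_kp(Kp: float, T: float = T_DEFAULT) -> float:
    """Standard free energy of partition, kJ/mol: -R*T*ln(Kp)/1000."""
    if Kp <= 0:
        raise ValueError(f"Kp must be positive, got {Kp}")
    return -R * T * math.log(Kp) / 1000.0


def kp_from_dG(dG: float, T: float = T_DEFAULT) -> float:
    """Inverse of :func:`dG_from_kp` (dG in kJ/mol)."""
    return math.exp(-dG * 1000.0 / (R * T))


def tds_from(dH: float, dG: float) -> float:
    """Entropic term TdS = dH - dG (all kJ/mol)."""
    return dH - dG


def summarize_log_kp(replicate_Kps: Sequence[float]) -> LogKpSummary:
    """Aggregate replicate Kp values on the log10 scale.

    Mean and (sample, ddof=1) standard deviation are computed on log10 Kp;
    the representative Kp is 10**mean, i.e. the geometric mean of the
    replicates. A single replicate gets sigma_log = 0.
    """
    kps = np.asarray(list(replicate_Kps), dtype=float)
    if kps.size == 0:
        raise ValueError("need at least one replicate Kp")
    if np.any(kps <= 0):
        raise ValueError("all Kp values must be positive")
    logs = np.log10(kps)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=1)) if kps.size > 1 else 0.0
    return LogKpSummary(n=int(kps.size), mu_log=mu, sigma_log=sigma, Kp_mu=10.0**mu)
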