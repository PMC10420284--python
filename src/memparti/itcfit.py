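"""ITC partition-model forward heats and fitting.

Lipid vesicles titrated into a dilute solute solution in a perfusion-type
calorimeter cell (constant overfilled volume V0). Each injection of volume v
displaces cell content, so after injection i both the already-injected lipid
and the solute are diluted by d_i = (1 - v/V0)**i:

    L_i = L_syr * (1 - d_i)          lipid in cell, mol/L
    D_i = D_0 * d_i                  solute in cell, mol/L
    f_i = Kp*Vbar*L_i / (1 + Kp*Vbar*L_i)   bound solute fraction
    n_i = V0 * D_i * f_i             bound moles
    q_i = dH * (n_i - n_{i-1}*(1 - v/V0)) + q_dil,   n_0 = 0

i.e. the heat of injection i is the enthalpy of the newly bound solute,
after accounting for bound solute physically displaced out of the cell, plus
a constant dilution heat. dH is in kJ/mol; heats are returned in joules.

Fitting is least squares over (log10 Kp, dH[, q_dil]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import T_DEFAULT, VBAR_POPC

__all__ = ["ITCProtocol", "ITCExperiment", "ITCFit", "model_heats", "fit_itc",
           "thermogram_summary"]


@dataclass(frozen=True)
class ITCProtocol:
    """Injection protocol of a lipid-into-solute uptake titration."""

    cell_volume: float = 1.4195e-3  # L (VP-ITC nominal)
    inj_volume: float = 10e-6  # L per injection
    n_inj: int = 25
    lipid_syringe: float = 10e-3  # mol/L
    solute_cell: float = 5e-6  # mol/L
    temperature: float = T_DEFAULT  # K

    def __post_init__(self):
        for name in ("cell_volume", "inj_volume", "lipid_syringe",
                     "solute_cell", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.inj_volume >= self.cell_volume:
            raise ValueError("inj_volume must be smaller than cell_volume")
        if self.n_inj < 1:
            raise ValueError("n_inj must be >= 1")

    def lipid_in_cell(self) -> np.ndarray:
        """Cell lipid concentration after each injection, mol/L."""
        i = np.arange(1, self.n_inj + 1)
        d = (1.0 - self.inj_volume / self.cell_volume) ** i
        return self.lipid_syringe * (1.0 - d)


@dataclass(frozen=True)
class ITCExperiment:
    """Integrated per-injection heats plus their protocol."""

    protocol: ITCProtocol
    heats: np.ndarray  # J per injection
    normalized: bool = False  # True if per mole of injectant

    def __post_init__(self):
        object.__setattr__(self, "heats", np.asarray(self.heats, dtype=float))
        if self.heats.size != self.protocol.n_inj:
            raise ValueError("len(heats) must equal protocol.n_inj")


@dataclass(frozen=True)
class ITCFit:
    Kp: float
    dH: float  # kJ/mol
    q_dil: float  # J per injection
    stderr: dict = field(default_factory=dict)
    residual_norm: float = 0.0
    identifiable: bool = True
    message: str = ""


def model_heats(
    protocol: ITCProtocol,
    Kp: float,
    dH: float,
    q_dil: float = 0.0,
    Vbar: float = VBAR_POPC,
) -> np.ndarray:
    """Forward per-injection heats (J) of the simple partition model."""
    if Kp <= 0:
        raise ValueError("Kp must be positive")
    V0, v = protocol.cell_volume, protocol.inj_volume
    keep = 1.0 - v / V0
    i = np.arange(1, protocol.n_inj + 1)
    d = keep**i
    L = protocol.lipid_syringe * (1.0 - d)
    D = protocol.solute_cell * d
    x = Kp * Vbar * L
    n = V0 * D * x / (1.0 + x)  # bound moles after each injection
    n_prev = np.concatenate(([0.0], n[:-1]))
    return dH * 1000.0 * (n - n_prev * keep) + q_dil


def fit_itc(
    exp: ITCExperiment,
    Vbar: float = VBAR_POPC,
    fit_q_dil: bool = False,
    drop_first: bool = False,
) -> ITCFit:
    """Least-squares fit of the partition model to integrated heats.

    Parameters are (log10 Kp, dH) and optionally a constant per-injection
    dilution heat. ``drop_first`` excludes the (often low-volume) first
    injection from the residuals while keeping it in the displacement
    bookkeeping.
    """
    heats = exp.heats
    if exp.protocol.n_inj < 5:
        raise ValueError("need >= 5 injections for a meaningful fit")
    mask = np.ones(heats.size, dtype=bool)
    if drop_first:
        mask[0] = False

    scale = max(np.max(np.abs(heats)), 1e-30)
    if np.ptp(heats[mask]) <= 1e-12 * scale:
        return ITCFit(Kp=1.0, dH=0.0, q_dil=float(np.mean(heats)), stderr={},
                      identifiable=False,
                      message="flat thermogram: Kp and dH unconstrained")

    Lmid = exp.protocol.lipid_in_cell()[exp.protocol.n_inj // 2]
    lk0 = math.log10(1.0 / (Vbar * Lmid))  # half-bound at mid-titration
    dH0 = float(np.sum(heats)) / max(
        exp.protocol.cell_volume * exp.protocol.solute_cell * 1000.0, 1e-30)

    def resid(theta):
        lk, dh = theta[0], theta[1]
        qd = theta[2] if fit_q_dil else 0.0
        m = model_heats(exp.protocol, 10.0**lk, dh, qd, Vbar)
        return (m - heats)[mask]

    best = None
    for start in (lk0 - 1.0, lk0, lk0 + 1.0):
        x0 = [start, dH0] + ([0.0] if fit_q_dil else [])
        res = least_squares(resid, x0, method="trf",
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise RuntimeError("ITC fit did not converge")

    lk, dh = best.x[0], best.x[1]
    qd = float(best.x[2]) if fit_q_dil else 0.0
    J = best.jac
    n, p = int(mask.sum()), J.shape[1]
    s2 = float(best.fun @ best.fun) / max(n - p, 1)
    sv = np.linalg.svd(J, compute_uv=False)
    identifiable, msg, se = True, "", {}
    if sv[0] <= 0 or sv[-1] / sv[0] < 1e-10:
        identifiable, msg = False, "singular Jacobian: parameters not jointly identifiable"
    else:
        cov = np.linalg.inv(J.T @ J) * s2
        sd = np.sqrt(np.diag(cov))
        se = {"log10_Kp": sd[0], "Kp": 10.0**lk * math.log(10.0) * sd[0], "dH": sd[1]}
        if fit_q_dil:
            se["q_dil"] = sd[2]
    return ITCFit(Kp=10.0**lk, dH=float(dh), q_dil=qd, stderr=se,
                  residual_norm=float(np.linalg.norm(best.fun)),
                  identifiable=identifiable, message=msg)


def thermogram_summary(exp: ITCExperiment, fit: ITCFit,
                       Vbar: float = VBAR_POPC) -> pd.DataFrame:
    """Per-injection table: observed, modeled, residual, cumulative lipid."""
    modeled = model_heats(exp.protocol, fit.Kp, fit.dH, fit.q_dil, Vbar)
    return pd.DataFrame({
        "injection": np.arange(1, exp.protocol.n_inj + 1),
        "observed_J": exp.heats,
        "modeled_J": modeled,
        "residual_J": exp.heats - modeled,
        "lipid_in_cell_M": exp.protocol.lipid_in_cell(),
    })
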