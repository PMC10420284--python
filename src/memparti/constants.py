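"""Physical constants and package-wide defaults.

All defaults applied implicitly by the higher-level workflows are collected
here so reports can echo them for provenance.
"""

#: Gas constant, J mol^-1 K^-1
R = 8.314

#: Default temperature, K (25 degC, the ITC bath temperature)
T_DEFAULT = 298.15

#: POPC molar volume, L/mol (dm^3/mol)
VBAR_POPC = 0.8

#: Bulk water boundary of the PMF reaction coordinate, nm
A_BULK_NM = 4.0

#: Avogadro constant, mol^-1
N_AVOGADRO = 6.02214076e23

#: Atomic mass unit, kg
AMU_KG = 1.66053906892e-27

#: Hydrogen-bond geometric criterion defaults
HBOND_DCUT_NM = 0.35
HBOND_ANGLE_DEG = 30.0

#: WHAM defaults
WHAM_NBINS = 200
WHAM_TOL = 1e-7
WHAM_MAX_ITER = 100_000


def RT_kJ(T: float = T_DEFAULT) -> float:
    """Thermal energy R*T in kJ/mol at temperature ``T`` (K)."""
    return R * T / 1000.0


#: Defaults table echoed into workflow reports.
DEFAULTS = {
    "R_J_per_mol_K": R,
    "T_K": T_DEFAULT,
    "Vbar_L_per_mol": VBAR_POPC,
    "a_nm": A_BULK_NM,
    "hbond_dcut_nm": HBOND_DCUT_NM,
    "hbond_angle_deg": HBOND_ANGLE_DEG,
    "wham_nbins": WHAM_NBINS,
    "wham_tol": WHAM_TOL,
    "wham_max_iter": WHAM_MAX_ITER,
}
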