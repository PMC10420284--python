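"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is seeded explicitly and touches no global random state, so
all downstream fitting/analysis stages can be tested by parameter recovery
without any laboratory or simulation data:

* fluorescence titrations from the forward partition isotherms, with
  multiplicative Gaussian noise (optical intensities span orders of
  magnitude across bands, so a coefficient-of-variation noise model is the
  natural instrument model);
* ITC thermograms from the perfusion-cell partition recursion, with a
  constant dilution heat and additive Gaussian noise;
* umbrella-sampling windows from overdamped (Euler-Maruyama) Langevin
  dynamics on a stated 1-D free-energy landscape plus the harmonic window
  bias — the 3-D membrane MD is collapsed onto the reaction coordinate,
  which is all WHAM consumes;
* toy bilayer trajectories with atoms placed at known depths, known
  long-axis orientation statistics, and hydrogen-bond geometries switched
  on in an exactly prescribed fraction of frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .constants import RT_kJ, VBAR_POPC
from .fluorfit import TitrationSeries, titration_model
from .itcfit import ITCExperiment, ITCProtocol, model_heats
from .pmfkit import UmbrellaWindow
from .trajkit import Trajectory

__all__ = [
    "FluorTruth",
    "BrownianSpec",
    "Placement",
    "HBondPairSpec",
    "ToyTrajSpec",
    "default_lipid_grid",
    "gen_fluor_titration",
    "gen_itc_heats",
    "gen_umbrella_windows",
    "gen_toy_trajectory",
]


def default_lipid_grid(n: int = 12, lo: float = 1e-5, hi: float = 2e-3) -> np.ndarray:
    """Default titration grid: n-point geometric ladder of lipid
    concentrations (mol/L). The lowest point is far below half-saturation
    for Kp ~ 10^3 and serves as the free-solute anchor."""
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class FluorTruth:
    """Ground truth of a fluorescence titration world.

    Endpoints: Iw/Im are the intensities with the probe fully aqueous /
    fully membrane-bound; rw/rm the corresponding anisotropies.
    alphaM_by_band maps wavelength-band labels to the membrane/water
    intensity ratio used to weight the anisotropy isotherm.
    """

    Kp: float = 1.8e3
    Iw: float = 1.0
    Im: float = 10.0
    rw: float = 0.05
    rm: float = 0.25
    alphaM_by_band: Mapping[str, float] = field(
        default_factory=lambda: {"450-470": 13.0, "470-490": 8.0, "490-510": 5.0})
    Vbar: float = VBAR_POPC
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.Kp <= 0 or self.Vbar <= 0:
            raise ValueError("Kp and Vbar must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if any(a <= 0 for a in self.alphaM_by_band.values()):
            raise ValueError("every alphaM must be positive")
        for r in (self.rw, self.rm):
            if not (-0.2 <= r <= 0.4):
                raise ValueError("anisotropy endpoints must lie in [-0.2, 0.4]")


def gen_fluor_titration(
    truth: FluorTruth,
    lipid_concs: Sequence[float] | None = None,
    kind: str = "intensity",
    band: str = "450-470",
    pH: float = 6.0,
) -> TitrationSeries:
    """Forward titration curve times (1 + eps), eps ~ N(0, noise_cv^2)."""
    lipid = default_lipid_grid() if lipid_concs is None else np.asarray(lipid_concs, float)
    if np.any(lipid < 0):
        raise ValueError("negative lipid concentration")
    if np.any(np.diff(lipid) < 0):
        raise ValueError("lipid concentrations must be ascending")
    if kind == "intensity":
        clean = titration_model(lipid, truth.Kp, truth.Iw, truth.Im, 1.0, truth.Vbar)
    elif kind == "anisotropy":
        if band not in truth.alphaM_by_band:
            raise KeyError(f"unknown band label {band!r}; have "
                           f"{sorted(truth.alphaM_by_band)}")
        aM = truth.alphaM_by_band[band]
        clean = titration_model(lipid, truth.Kp, truth.rw, truth.rm, aM, truth.Vbar)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    rng = np.random.default_rng(truth.seed)
    signal = clean * (1.0 + truth.noise_cv * rng.standard_normal(lipid.size))
    return TitrationSeries(lipid=lipid, signal=signal, kind=kind, band=band, pH=pH)


def gen_itc_heats(
    protocol: ITCProtocol,
    Kp: float,
    dH: float,
    q_dil: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    Vbar: float = VBAR_POPC,
) -> ITCExperiment:
    """Per-injection heats from the partition forward model plus additive
    Gaussian noise (J). dH in kJ/mol."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    heats = model_heats(protocol, Kp, dH, q_dil, Vbar)
    rng = np.random.default_rng(seed)
    heats = heats + noise_sd * rng.standard_normal(heats.size)
    return ITCExperiment(protocol=protocol, heats=heats)


@dataclass(frozen=True)
class BrownianSpec:
    """Overdamped 1-D Langevin sampling of G(z) under harmonic window biases.

    ``potential`` maps z (nm, ndarray-friendly) to kJ/mol on [0, a]. The
    integrator is Euler-Maruyama: dz = -(D/RT) G'_tot dt + sqrt(2 D dt) xi.
    Defaults mirror a 0.1 nm window ladder restrained at
    3000 kJ mol^-1 nm^-2 with a small-molecule aqueous diffusivity.
    """

    potential: Callable[[np.ndarray], np.ndarray]
    centers: Sequence[float] = tuple(np.round(np.arange(0.0, 4.0 + 1e-9, 0.1), 3))
    force_const: float = 3000.0  # kJ mol^-1 nm^-2
    diffusion: float = 1e-3  # nm^2/ps
    dt: float = 0.01  # ps
    n_steps: int = 30_000
    discard_frac: float = 1.0 / 3.0
    temperature: float = 298.0
    stride: int = 1
    n_chains: int = 8
    a: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.force_const <= 0:
            raise ValueError("force_const must be positive")
        if not (0.0 <= self.discard_frac < 1.0):
            raise ValueError("discard_frac must lie in [0, 1)")
        c = np.asarray(self.centers, float)
        if np.any(c < 0.0) or np.any(c > self.a):
            raise ValueError(f"window centers must lie in [0, {self.a}]")
        rms_step = math.sqrt(2.0 * self.diffusion * self.dt)
        spacing = float(np.min(np.diff(np.sort(c)))) if c.size > 1 else self.a
        if rms_step >= spacing:
            raise ValueError(
                f"per-step RMS displacement {rms_step:.3g} nm >= window "
                f"spacing {spacing:.3g} nm; reduce dt or diffusion")


def gen_umbrella_windows(spec: BrownianSpec) -> list[UmbrellaWindow]:
    """Simulate every window of ``spec`` and return post-discard samples.

    All windows advance in lockstep from independent seeds derived from
    ``spec.seed``; two identical specs give bit-identical samples. For a
    quadratic total potential the retained samples are Gaussian with mean at
    the biased minimum and variance RT/k_total.
    """
    rt = RT_kJ(spec.temperature)
    centers = np.asarray(spec.centers, float)
    rng = np.random.default_rng(spec.seed)
    # n_chains independent replicas per window advance in one flat vector;
    # equilibrium sampling is exchangeable across chains, so their post-
    # discard samples pool into one window time series.
    c_rep = np.repeat(centers, spec.n_chains)
    z = c_rep.copy()
    h = 1e-5  # nm, central-difference step for G'

    def grad_total(z):
        gp = (spec.potential(z + h) - spec.potential(z - h)) / (2.0 * h)
        return gp + spec.force_const * (z - c_rep)

    mob = spec.diffusion / rt * spec.dt
    sig = math.sqrt(2.0 * spec.diffusion * spec.dt)
    n_discard = int(spec.discard_frac * spec.n_steps)
    kept = []
    for step in range(spec.n_steps):
        z = z - mob * grad_total(z) + sig * rng.standard_normal(z.size)
        if step >= n_discard and (step - n_discard) % spec.stride == 0:
            kept.append(z.copy())
    # (n_kept, n_windows, n_chains) -> chain-major per window
    samples = np.asarray(kept).reshape(len(kept), centers.size, spec.n_chains)
    samples = samples.transpose(1, 2, 0).reshape(centers.size, -1)
    dt_sample = spec.dt * spec.stride
    t_discard = n_discard * spec.dt
    return [
        UmbrellaWindow(center=float(c), force_const=spec.force_const,
                       samples=samples[j], sample_interval=dt_sample,
                       discarded_time=t_discard)
        for j, c in enumerate(centers)
    ]


@dataclass(frozen=True)
class Placement:
    """One atom per molecule placed by a z rule each frame.

    rule: ("fixed", z_nm) or ("gaussian", mu_nm, sigma_nm).
    ``group`` becomes the atom's species label.
    """

    name: str
    mass: float
    group: str
    rule: tuple

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.rule[0] not in ("fixed", "gaussian"):
            raise ValueError(f"unknown placement rule {self.rule[0]!r}")
        if self.rule[0] == "gaussian" and self.rule[2] < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class HBondPairSpec:
    """A donor(N-H)/acceptor(O) pair bonded in exactly ``occupancy`` of frames."""

    donor: str
    hydrogen: str
    acceptor: str
    occupancy: float

    def __post_init__(self):
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy must lie in [0, 1], got {self.occupancy}")


@dataclass(frozen=True)
class ToyTrajSpec:
    """Recipe for a toy bilayer trajectory with known observables.

    ``axis_angle_dist``: ("delta", theta_deg), ("gaussian", mu_deg,
    sigma_deg) or ("uniform_sphere",) for the long-axis tilt of each
    molecule; the axis is a TAIL/HEAD atom pair of length ``axis_length``
    anchored at z = ``axis_tail_z`` (sign selects the leaflet).
    """

    box: tuple[float, float, float] = (20.0, 20.0, 10.0)
    n_frames: int = 100
    placements: tuple[Placement, ...] = ()
    n_molecules: int = 1
    axis_angle_dist: tuple | None = None
    axis_tail_z: float = 1.0
    axis_length: float = 0.5
    hbond_pairs: tuple[HBondPairSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1 or self.n_molecules < 1:
            raise ValueError("n_frames and n_molecules must be >= 1")
        if any(b <= 0 for b in self.box):
            raise ValueError("box dimensions must be positive")


def _alternation_mask(n_frames: int, occupancy: float) -> np.ndarray:
    """Deterministic Bresenham alternation: exactly round(occ*n) True values,
    spread as evenly as possible."""
    k = int(round(occupancy * n_frames))
    i = np.arange(n_frames)
    return ((i + 1) * k) // n_frames > (i * k) // n_frames


def _draw_theta(dist: tuple, size: int, rng) -> np.ndarray:
    """Tilt angles in degrees from the requested distribution."""
    if dist[0] == "delta":
        return np.full(size, float(dist[1]))
    if dist[0] == "gaussian":
        return np.clip(rng.normal(dist[1], dist[2], size), 0.0, 180.0)
    if dist[0] == "uniform_sphere":
        return np.degrees(np.arccos(rng.uniform(-1.0, 1.0, size)))
    raise ValueError(f"unknown axis angle distribution {dist[0]!r}")


def gen_toy_trajectory(spec: ToyTrajSpec) -> Trajectory:
    """Assemble a trajectory realising the placements, tilt statistics and
    H-bond occupancies of ``spec`` exactly.

    Bonded H-bond frames satisfy the default geometric criterion with a wide
    margin (D-A 0.28 nm, H on the D-A axis); unbonded frames put the
    acceptor at 0.6 nm >= 1.5x the 0.35 nm cutoff. Each pair and each
    molecule occupies its own lateral slot so pairs never cross-bond.
    """
    rng = np.random.default_rng(spec.seed)
    F, M = spec.n_frames, spec.n_molecules
    if spec.hbond_pairs:
        # lateral slots must stay >2x the H-bond cutoff apart, also across
        # the periodic boundary
        x_extent = 3.0 + 2.5 * (len(spec.hbond_pairs) - 1) + 0.6
        y_extent = 4.0 + 1.0 * (M - 1)
        if x_extent + 0.7 > spec.box[0] or y_extent + 0.7 > spec.box[1]:
            raise ValueError(
                "impossible geometry request: H-bond pair layout "
                f"({x_extent:.1f} x {y_extent:.1f} nm) does not fit the "
                f"box {spec.box[:2]}; enlarge the box or reduce pairs")
    names, masses, mol_ids, species = [], [], [], []
    columns = []  # per-atom (F, 3) coordinate arrays

    def add_atom(name, mass, mol, spc, xyz):
        names.append(name)
        masses.append(mass)
        mol_ids.append(mol)
        species.append(spc)
        columns.append(xyz)

    for m in range(M):
        for pi, p in enumerate(spec.placements):
            if p.rule[0] == "fixed":
                z = np.full(F, float(p.rule[1]))
            else:
                z = rng.normal(p.rule[1], p.rule[2], F)
            xyz = np.empty((F, 3))
            xyz[:, 0] = 1.0 + 0.7 * pi
            xyz[:, 1] = 1.0 + 0.9 * m
            xyz[:, 2] = z
            add_atom(p.name, p.mass, m, p.group, xyz)

        if spec.axis_angle_dist is not None:
            theta = np.radians(_draw_theta(spec.axis_angle_dist, F, rng))
            phi = rng.uniform(0.0, 2.0 * math.pi, F)
            outward = 1.0 if spec.axis_tail_z >= 0 else -1.0
            tail = np.empty((F, 3))
            tail[:, 0] = 2.0 + 0.9 * m
            tail[:, 1] = 2.0 + 0.9 * m
            tail[:, 2] = spec.axis_tail_z
            L = spec.axis_length
            head = tail + L * np.stack([
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
                np.cos(theta) * outward,
            ], axis=1)
            add_atom("TAIL", 10.0, m, "solute", tail)
            add_atom("HEAD", 10.0, m, "solute", head)

        for pp, pair in enumerate(spec.hbond_pairs):
            bonded = _alternation_mask(F, pair.occupancy)
            base = np.array([3.0 + 2.5 * pp, 4.0 + 1.0 * m, 1.0])
            donor = np.tile(base, (F, 1))
            hydrogen = donor + np.array([0.1, 0.0, 0.0])
            acceptor = donor.copy()
            acceptor[:, 0] += np.where(bonded, 0.28, 0.60)
            add_atom(pair.donor, 14.0, m, "solute", donor)
            add_atom(pair.hydrogen, 1.0, m, "solute", hydrogen)
            add_atom(pair.acceptor, 16.0, 100_000 + pp * M + m, "lipid", acceptor)

    if not columns:
        raise ValueError("spec produces no atoms")
    coords = np.stack(columns, axis=1)  # (F, n_atoms, 3)
    boxes = np.tile(np.asarray(spec.box, float), (F, 1))
    return Trajectory(coords=coords, boxes=boxes, names=np.array(names),
                      masses=np.array(masses, float), mol_ids=np.array(mol_ids),
                      species=np.array(species))
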