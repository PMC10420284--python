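"""Observables of solute/bilayer trajectories.

Operates on plain in-memory trajectories (frames of named, massed atoms in a
rectangular box) and computes the unrestrained-MD observables used to
characterise how an amphiphilic solute sits in a lipid bilayer:

* mass-density profiles along the bilayer normal (z),
* per-group transverse positions |z| with across-molecule confidence
  intervals,
* tilt of a solute-defined long axis relative to the outward leaflet normal
  (theta < 90 deg means the head atom points toward water),
* donor-acceptor hydrogen-bond fractional frequencies (mean bonds per frame
  per molecule) classified by acceptor chemistry, with per-donor and
  per-class summaries.

Conventions: distances in nm, masses in amu, densities in kg/m^3. Minimum
image is applied in x/y; z is treated as unwrapped with the bilayer centered
by construction. All observables are invariant to rigid translation of each
frame (positions are taken relative to the bilayer center of mass where one
is defined, otherwise to the z = 0 plane).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import AMU_KG, HBOND_ANGLE_DEG, HBOND_DCUT_NM

__all__ = [
    "Trajectory",
    "GroupSpec",
    "HBondSummary",
    "TiltDistribution",
    "DensityProfile",
    "com_z_series",
    "mass_density_profile",
    "group_positions",
    "tilt_distribution",
    "hbond_frequencies",
    "per_donor_frequency",
    "acceptor_class_fractions",
]


@dataclass(frozen=True)
class Trajectory:
    """Multi-frame coordinates with a parallel atom table.

    coords: (n_frames, n_atoms, 3) nm; boxes: (n_frames, 3) nm.
    names/masses/mol_ids/species are per-atom and constant across frames.
    """

    coords: np.ndarray
    boxes: np.ndarray
    names: np.ndarray  # str per atom
    masses: np.ndarray  # amu
    mol_ids: np.ndarray  # int per atom
    species: np.ndarray  # str per atom, e.g. "solute" | "lipid" | "water"

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        object.__setattr__(self, "boxes", np.asarray(self.boxes, dtype=float))
        for name in ("names", "masses", "mol_ids", "species"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        n_at = self.coords.shape[1]
        for name in ("names", "masses", "mol_ids", "species"):
            if getattr(self, name).shape != (n_at,):
                raise ValueError(f"{name} must have one entry per atom")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if np.any(self.boxes <= 0):
            raise ValueError("box dimensions must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, names=None, species=None, mol_id=None) -> np.ndarray:
        """Boolean atom mask by name set, species label and/or molecule id."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if names is not None:
            mask &= np.isin(self.names, list(names))
        if species is not None:
            mask &= self.species == species
        if mol_id is not None:
            mask &= self.mol_ids == mol_id
        return mask

    def molecule_ids(self, species: str) -> np.ndarray:
        return np.unique(self.mol_ids[self.species == species])


@dataclass(frozen=True)
class GroupSpec:
    """Named atom groups, the long-axis atom pair, and H-bond chemistry."""

    com_groups: Mapping[str, frozenset] = field(default_factory=dict)
    axis_pair: tuple[str, str] | None = None  # (tail, head); head = piperazine end
    donors: Sequence[tuple[str, str]] = ()  # (donor N name, bonded H name)
    acceptor_classes: Mapping[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        if self.axis_pair is not None and self.axis_pair[0] == self.axis_pair[1]:
            raise ValueError("axis atoms must be distinct")

    def validate_against(self, traj: Trajectory) -> None:
        known = set(traj.names.tolist())
        wanted = set()
        for g in self.com_groups.values():
            wanted |= set(g)
        if self.axis_pair:
            wanted |= set(self.axis_pair)
        for d, h in self.donors:
            wanted |= {d, h}
        for accs in self.acceptor_classes.values():
            wanted |= set(accs)
        missing = wanted - known
        if missing:
            raise ValueError(f"atom names not in trajectory: {sorted(missing)}")


@dataclass(frozen=True)
class DensityProfile:
    z_centers: np.ndarray  # nm
    density: np.ndarray  # kg/m^3
    bin_width: float  # nm


@dataclass(frozen=True)
class TiltDistribution:
    theta_bins: np.ndarray  # deg, bin centers on [0, 180]
    density: np.ndarray  # probability density per degree
    mean_theta: float  # deg


@dataclass(frozen=True)
class HBondSummary:
    """freq[donor_label][class] = mean bonds per frame per molecule."""

    freq: pd.DataFrame  # rows: donor labels, columns: acceptor classes
    n_donors: int

    @property
    def class_totals(self) -> pd.Series:
        return self.freq.sum(axis=0)

    @property
    def donor_totals(self) -> pd.Series:
        return self.freq.sum(axis=1)

    @property
    def grand_total(self) -> float:
        return float(self.freq.values.sum())


def _bilayer_com_z(traj: Trajectory, bilayer_species: str | None) -> np.ndarray:
    """Per-frame bilayer COM z; zeros if no bilayer species is given."""
    if bilayer_species is None:
        return np.zeros(traj.n_frames)
    mask = traj.species == bilayer_species
    if not np.any(mask):
        return np.zeros(traj.n_frames)
    m = traj.masses[mask]
    return traj.coords[:, mask, 2] @ m / m.sum()


def com_z_series(
    traj: Trajectory,
    group: Sequence[str],
    molecule: int,
    bilayer_species: str | None = "lipid",
) -> np.ndarray:
    """Mass-weighted COM z of ``group`` atoms of one molecule, per frame,
    relative to the bilayer COM (signed)."""
    mask = traj.select(names=group, mol_id=molecule)
    if not np.any(mask):
        raise ValueError(f"empty selection: group {list(group)} in molecule {molecule}")
    m = traj.masses[mask]
    z = traj.coords[:, mask, 2] @ m / m.sum()
    return z - _bilayer_com_z(traj, bilayer_species)


def mass_density_profile(
    traj: Trajectory,
    species: str,
    bin_width: float = 0.1,
    z_range: tuple[float, float] | None = None,
    bilayer_species: str | None = "lipid",
) -> DensityProfile:
    """Frame-averaged mass density (kg/m^3) of ``species`` along z.

    The integral of density over z times the box cross-section equals the
    total species mass per frame (mass conservation), provided ``z_range``
    covers all positions.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask = traj.species == species
    ref = _bilayer_com_z(traj, bilayer_species)
    z = traj.coords[:, mask, 2] - ref[:, None]
    if z_range is None:
        half = traj.boxes[:, 2].max() / 2.0
        lo = math.floor(-half / bin_width) * bin_width
        hi = math.ceil(half / bin_width) * bin_width
    else:
        lo, hi = z_range
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    masses = np.broadcast_to(traj.masses[mask], z.shape)
    hist, _ = np.histogram(z.ravel(), bins=edges, weights=masses.ravel())
    hist = hist / traj.n_frames  # amu per bin per frame
    area = float(np.mean(traj.boxes[:, 0] * traj.boxes[:, 1]))  # nm^2
    vol_m3 = area * bin_width * 1e-27
    density = hist * AMU_KG / vol_m3
    return DensityProfile(z_centers=0.5 * (edges[:-1] + edges[1:]),
                          density=density, bin_width=bin_width)


def group_positions(
    traj: Trajectory,
    groups: Mapping[str, Sequence[str]],
    molecules: Sequence[int],
    bilayer_species: str | None = "lipid",
    exclude: Sequence[int] = (),
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Mean transverse distance |z| to the bilayer center per group.

    Per molecule, |z| is time-averaged first; the table then reports the
    across-molecule mean and a t-based confidence interval with
    n = number of molecules, so leaflets pool and molecules are the unit of
    replication. ``exclude`` drops flagged molecules (e.g. aggregates).
    """
    mols = [m for m in molecules if m not in set(exclude)]
    if not mols:
        raise ValueError("no molecules left after exclusion")
    rows = []
    for label, names in groups.items():
        per_mol = []
        for m in mols:
            z = com_z_series(traj, names, m, bilayer_species)
            per_mol.append(np.mean(np.abs(z)))
        per_mol = np.asarray(per_mol)
        n = per_mol.size
        mean = float(np.mean(per_mol))
        if n > 1:
            sem = float(np.std(per_mol, ddof=1) / math.sqrt(n))
            half = sem * stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
        else:
            half = 0.0
        rows.append({"group": label, "mean_abs_z_nm": mean,
                     "ci_half_width_nm": half, "n_molecules": n})
    return pd.DataFrame(rows).set_index("group")


def tilt_distribution(
    traj: Trajectory,
    axis_pair: tuple[str, str],
    molecules: Sequence[int],
    bin_width_deg: float = 5.0,
    bilayer_species: str | None = "lipid",
    solute_species: str = "solute",
    exclude: Sequence[int] = (),
) -> TiltDistribution:
    """Histogram of the long-axis tilt over frames and molecules.

    theta is the angle between (head - tail) and the outward normal of the
    molecule's leaflet (+z in the upper leaflet, -z in the lower, judged by
    the sign of the molecule COM z each frame), so theta < 90 deg always
    means the head points toward water.
    """
    tail_name, head_name = axis_pair
    ref = _bilayer_com_z(traj, bilayer_species)
    mols = [m for m in molecules if m not in set(exclude)]
    if not mols:
        raise ValueError("no molecules left after exclusion")
    thetas = []
    for m in mols:
        tail = traj.select(names=[tail_name], mol_id=m)
        head = traj.select(names=[head_name], mol_id=m)
        if tail.sum() != 1 or head.sum() != 1:
            raise ValueError(f"axis atoms not uniquely resolvable in molecule {m}")
        vec = traj.coords[:, head, :][:, 0, :] - traj.coords[:, tail, :][:, 0, :]
        norm = np.linalg.norm(vec, axis=1)
        if np.any(norm == 0):
            raise ValueError(f"zero-length axis vector in molecule {m}")
        sol = traj.select(species=solute_species, mol_id=m)
        sel = sol if np.any(sol) else traj.select(mol_id=m)
        mm = traj.masses[sel]
        com_z = traj.coords[:, sel, 2] @ mm / mm.sum() - ref
        outward = np.where(com_z >= 0, 1.0, -1.0)
        cos_t = np.clip(vec[:, 2] * outward / norm, -1.0, 1.0)
        thetas.append(np.degrees(np.arccos(cos_t)))
    theta = np.concatenate(thetas)
    edges = np.arange(0.0, 180.0 + 0.5 * bin_width_deg, bin_width_deg)
    hist, _ = np.histogram(theta, bins=edges, density=True)
    return TiltDistribution(theta_bins=0.5 * (edges[:-1] + edges[1:]),
                            density=hist, mean_theta=float(np.mean(theta)))


def _min_image_xy(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = d.copy()
    for k in (0, 1):
        d[..., k] -= box[k] * np.round(d[..., k] / box[k])
    return d


def hbond_frequencies(
    traj: Trajectory,
    donors: Sequence[tuple[str, str]],
    acceptor_classes: Mapping[str, Sequence[str]],
    d_cut: float = HBOND_DCUT_NM,
    angle_cut: float = HBOND_ANGLE_DEG,
    donor_species: str = "solute",
    exclude: Sequence[int] = (),
) -> HBondSummary:
    """Fractional H-bond frequency per donor group and acceptor class.

    A donor-acceptor pair is bonded in a frame iff the donor-acceptor
    distance is <= d_cut (nm) and the H-donor-acceptor angle is <= angle_cut
    (deg). Each entry is the bonded-pair count averaged over frames and over
    donor molecules (mean bonds per frame per molecule), so entries can
    exceed 1 when a donor reaches several acceptors of one class.
    """
    if d_cut <= 0 or angle_cut <= 0:
        raise ValueError("cutoffs must be positive")
    cos_cut = math.cos(math.radians(angle_cut))
    mols = [m for m in traj.molecule_ids(donor_species) if m not in set(exclude)]
    if not mols:
        raise ValueError(f"no donor molecules of species {donor_species!r}")
    classes = list(acceptor_classes)
    acc_masks = {c: traj.select(names=acceptor_classes[c]) for c in classes}
    freq = np.zeros((len(donors), len(classes)))
    n_frames = traj.n_frames
    for di, (d_name, h_name) in enumerate(donors):
        for m in mols:
            d_mask = traj.select(names=[d_name], mol_id=m)
            h_mask = traj.select(names=[h_name], mol_id=m)
            if d_mask.sum() == 0:
                continue  # donor absent in this form
            if h_mask.sum() != d_mask.sum():
                raise ValueError(
                    f"donor {d_name} in molecule {m} lacks a matching H {h_name}")
            D = traj.coords[:, d_mask, :]  # (F, nd, 3)
            H = traj.coords[:, h_mask, :]
            for ci, c in enumerate(classes):
                A = traj.coords[:, acc_masks[c], :]  # (F, na, 3)
                if A.shape[1] == 0:
                    continue
                box = traj.boxes
                dDA = A[:, None, :, :] - D[:, :, None, :]  # (F, nd, na, 3)
                for k in (0, 1):
                    dDA[..., k] -= box[:, None, None, k] * np.round(
                        dDA[..., k] / box[:, None, None, k])
                rDA = np.linalg.norm(dDA, axis=-1)
                dDH = H[:, :, None, :] - D[:, :, None, :]
                rDH = np.linalg.norm(dDH, axis=-1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    cos_hda = np.einsum("fdak,fdak->fda", dDH, dDA) / (rDH * rDA)
                bonded = (rDA <= d_cut) & (cos_hda >= cos_cut)
                freq[di, ci] += bonded.sum() / (n_frames * len(mols))
    df = pd.DataFrame(freq, index=[d for d, _ in donors], columns=classes)
    return HBondSummary(freq=df, n_donors=len(donors))


def per_donor_frequency(summary: HBondSummary) -> float:
    """Grand-total H-bond frequency divided by the number of donor groups."""
    if summary.n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    return summary.grand_total / summary.n_donors


def acceptor_class_fractions(summary: HBondSummary) -> dict:
    """Percentage of the grand total contributed by each acceptor class."""
    total = summary.grand_total
    if total <= 0:
        raise ValueError("zero total H-bond frequency")
    return {c: 100.0 * v / total for c, v in summary.class_totals.items()}
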