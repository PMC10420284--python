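"""File formats and workflow orchestration.

Text dialects (all round-trip with the writers here):

* titration CSV: columns ``lipid_M, signal, kind, band, pH`` — one file can
  hold several series, split on distinct (kind, band, pH);
* ITC CSV: columns ``injection, heat, unit`` with heats in J, mJ, uJ, cal,
  mcal or ucal (converted to J on read); the protocol lives in a JSON
  config;
* umbrella windows: a metadata CSV (``file, center, force_const``) naming
  one two-column whitespace text file (time_ps, z_nm) per window —
  pull-file dialect; a time discard is applied on read;
* PMF: three-column whitespace text (z_nm, dG_kJmol, err_kJmol);
* trajectories: multi-frame concatenated GRO, or a plain XYZ-with-box
  dialect (comment line carries the box).

``run_workflow`` chains the stages into the two end-to-end analyses
(experimental partition fitting; simulation PMF analysis) plus the
generators, and writes a JSON report echoing every default applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fluorfit, itcfit, pmfkit, synthdata, thermoagg
from .constants import DEFAULTS, T_DEFAULT, VBAR_POPC
from .fluorfit import TitrationSeries
from .itcfit import ITCExperiment, ITCProtocol
from .pmfkit import UmbrellaWindow
from .trajkit import Trajectory

__all__ = [
    "read_titration_csv", "write_titration_csv",
    "read_itc_csv", "write_itc_csv",
    "read_windows", "write_windows",
    "read_pmf", "write_pmf",
    "read_gro", "write_gro", "read_xyz", "write_xyz",
    "RunConfig", "run_workflow",
]

_CAL = 4.184
_HEAT_TO_J = {"J": 1.0, "mJ": 1e-3, "uJ": 1e-6,
              "cal": _CAL, "mcal": _CAL * 1e-3, "ucal": _CAL * 1e-6}


# ---------------------------------------------------------------- titrations

def read_titration_csv(path) -> list[TitrationSeries]:
    """Read titration series, grouped by (kind, band, pH)."""
    df = pd.read_csv(path)
    required = {"lipid_M", "signal", "kind", "band", "pH"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    for col in ("lipid_M", "signal", "pH"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, data row {row + 1}")
        df[col] = pd.to_numeric(df[col])
    out = []
    for (kind, band, pH), g in df.groupby(["kind", "band", "pH"], sort=True):
        g = g.sort_values("lipid_M")
        out.append(TitrationSeries(
            lipid=g["lipid_M"].to_numpy(), signal=g["signal"].to_numpy(),
            kind=str(kind), band=str(band), pH=float(pH)))
    return out


def write_titration_csv(path, series_list) -> None:
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "lipid_M": s.lipid, "signal": s.signal, "kind": s.kind,
            "band": s.band, "pH": s.pH}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ----------------------------------------------------------------------- ITC

def read_itc_csv(path, protocol: ITCProtocol) -> ITCExperiment:
    """Read integrated per-injection heats; converts the unit column to J."""
    df = pd.read_csv(path)
    missing = {"injection", "heat", "unit"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    df = df.sort_values("injection")
    heats = np.empty(len(df))
    for i, (h, u) in enumerate(zip(df["heat"], df["unit"])):
        if u not in _HEAT_TO_J:
            raise ValueError(f"{path}: unknown heat unit {u!r} "
                             f"(know {sorted(_HEAT_TO_J)})")
        heats[i] = float(h) * _HEAT_TO_J[u]
    return ITCExperiment(protocol=protocol, heats=heats)


def write_itc_csv(path, exp: ITCExperiment, unit: str = "J") -> None:
    f = _HEAT_TO_J[unit]
    pd.DataFrame({
        "injection": np.arange(1, exp.heats.size + 1),
        "heat": exp.heats / f,
        "unit": unit,
    }).to_csv(path, index=False)


# ------------------------------------------------------------------- windows

def read_windows(meta_path, discard_frac: float = 0.0) -> list[UmbrellaWindow]:
    """Read umbrella windows from a metadata CSV plus per-window pull files.

    Sample files are two-column whitespace text (time_ps, z_nm), paths
    relative to the metadata file. ``discard_frac`` drops the first fraction
    of each window's time span (e.g. 1/3 of a 120 ns run keeps the last
    80 ns).
    """
    meta_path = Path(meta_path)
    meta = pd.read_csv(meta_path)
    missing = {"file", "center", "force_const"} - set(meta.columns)
    if missing:
        raise ValueError(f"{meta_path}: missing columns {sorted(missing)}")
    windows = []
    for _, row in meta.iterrows():
        fpath = meta_path.parent / str(row["file"])
        if float(row["force_const"]) <= 0:
            raise ValueError(f"{meta_path}: non-positive force constant for "
                             f"{row['file']}")
        if not fpath.exists():
            raise FileNotFoundError(f"window sample file missing: {fpath}")
        data = (np.loadtxt(fpath, ndmin=2) if fpath.stat().st_size > 0
                else np.empty((0, 2)))
        if data.size == 0:
            raise ValueError(f"empty sample file for window at center "
                             f"{row['center']}: {fpath}")
        t, z = data[:, 0], data[:, 1]
        t0, t1 = t.min(), t.max()
        cut = t0 + discard_frac * (t1 - t0)
        keep = t > cut if discard_frac > 0 else np.ones(t.size, bool)
        if not np.any(keep):
            raise ValueError(f"no samples left after discard in {fpath}")
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        windows.append(UmbrellaWindow(
            center=float(row["center"]), force_const=float(row["force_const"]),
            samples=z[keep], sample_interval=dt, discarded_time=float(cut)))
    return windows


def write_windows(out_dir, windows, prefix: str = "window") -> Path:
    """Write pull files plus metadata CSV; returns the metadata path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        fname = f"{prefix}_{i:03d}.xvg"
        np.savetxt(out_dir / fname, np.column_stack([w.times(), w.samples]),
                   fmt="%.6f")
        rows.append({"file": fname, "center": w.center,
                     "force_const": w.force_const})
    meta = out_dir / f"{prefix}_meta.csv"
    pd.DataFrame(rows).to_csv(meta, index=False)
    return meta


# ----------------------------------------------------------------------- PMF

def write_pmf(path, profile: pmfkit.PMFProfile) -> None:
    err = profile.boot_err if profile.boot_err is not None else np.full_like(profile.dG, np.nan)
    np.savetxt(path, np.column_stack([profile.z_grid, profile.dG, err]),
               fmt="%.6f", header="z_nm dG_kJmol err_kJmol")


def read_pmf(path, temperature: float = T_DEFAULT) -> pmfkit.PMFProfile:
    data = np.loadtxt(path, ndmin=2)
    z, dG = data[:, 0], data[:, 1]
    err = data[:, 2] if data.shape[1] > 2 else None
    ok = np.isfinite(dG)
    anchor = float(z[ok][np.argmin(np.abs(dG[ok]))]) if ok.any() else 0.0
    return pmfkit.PMFProfile(z_grid=z, dG=dG, anchor=anchor,
                             temperature=temperature, boot_err=err)


# ---------------------------------------------------------------- trajectory

def write_gro(path, traj: Trajectory, title: str = "memparti toy trajectory") -> None:
    """Concatenated multi-frame GRO (positions in nm, fixed-width)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{title}, frame {f}\n{traj.n_atoms:5d}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[f, a]
                fh.write(f"{int(traj.mol_ids[a]) % 100000:5d}"
                         f"{str(traj.species[a])[:5]:<5s}"
                         f"{str(traj.names[a])[:5]:>5s}"
                         f"{(a + 1) % 100000:5d}"
                         f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
            bx, by, bz = traj.boxes[f]
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


def read_gro(path, masses: dict | None = None) -> Trajectory:
    """Read a (multi-frame) GRO file.

    GRO does not carry masses; ``masses`` maps atom name to amu (default
    1.0). Residue names become species labels, residue numbers molecule ids.
    """
    frames, boxes = [], []
    names = species = mol_ids = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i + 1])
        block = lines[i + 2: i + 2 + n]
        coords = np.empty((n, 3))
        nm, sp, mi = [], [], []
        for j, ln in enumerate(block):
            mi.append(int(ln[0:5]))
            sp.append(ln[5:10].strip())
            nm.append(ln[10:15].strip())
            coords[j] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        box = [float(v) for v in lines[i + 2 + n].split()[:3]]
        frames.append(coords)
        boxes.append(box)
        if names is None:
            names, species, mol_ids = nm, sp, mi
        i += n + 3
    if not frames:
        raise ValueError(f"{path}: no frames")
    names = np.array(names)
    m = np.array([(masses or {}).get(nm, 1.0) for nm in names], float)
    return Trajectory(coords=np.stack(frames), boxes=np.array(boxes, float),
                      names=names, masses=m,
                      mol_ids=np.array(mol_ids), species=np.array(species))


def write_xyz(path, traj: Trajectory) -> None:
    """Plain per-frame XYZ dialect; the comment line carries ``box= Lx Ly Lz``
    and columns are name x y z mass mol_id species (nm, amu)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            bx, by, bz = traj.boxes[f]
            fh.write(f"box= {bx:.6f} {by:.6f} {bz:.6f}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[f, a]
                fh.write(f"{traj.names[a]} {x:.6f} {y:.6f} {z:.6f} "
                         f"{traj.masses[a]:.6f} {int(traj.mol_ids[a])} "
                         f"{traj.species[a]}\n")


def read_xyz(path) -> Trajectory:
    frames, boxes = [], []
    names = masses = mol_ids = species = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        box = [float(v) for v in lines[i + 1].split()[1:4]]
        block = lines[i + 2: i + 2 + n]
        coords = np.empty((n, 3))
        nm, ms, mi, sp = [], [], [], []
        for j, ln in enumerate(block):
            parts = ln.split()
            nm.append(parts[0])
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            ms.append(float(parts[4]))
            mi.append(int(parts[5]))
            sp.append(parts[6])
        frames.append(coords)
        boxes.append(box)
        if names is None:
            names, masses, mol_ids, species = nm, ms, mi, sp
        i += n + 2
    if not frames:
        raise ValueError(f"{path}: no frames")
    return Trajectory(coords=np.stack(frames), boxes=np.array(boxes, float),
                      names=np.array(names), masses=np.array(masses, float),
                      mol_ids=np.array(mol_ids), species=np.array(species))


# ------------------------------------------------------------------ workflow

@dataclass
class RunConfig:
    """Validated configuration of one workflow run."""

    workflow: str  # fluor | itc | pmf | simulate-fluor | simulate-itc | simulate-umbrella
    inputs: dict = field(default_factory=dict)  # role -> path
    params: dict = field(default_factory=dict)  # overrides of DEFAULTS
    out_dir: str = "."
    seed: int = 0

    _WORKFLOWS = ("fluor", "itc", "pmf",
                  "simulate-fluor", "simulate-itc", "simulate-umbrella")

    def __post_init__(self):
        if self.workflow not in self._WORKFLOWS:
            raise ValueError(f"unknown workflow {self.workflow!r}; "
                             f"choose from {self._WORKFLOWS}")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        for role, p in self.inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"input {role!r}: {p} does not exist")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _fit_fluor_workflow(cfg, params):
    vbar = params["Vbar_L_per_mol"]
    series = read_titration_csv(cfg.inputs["titrations"])
    alpha = cfg.params.get("alphaM_by_band", {})
    results = []
    for s in series:
        if s.kind == "intensity":
            fit = fluorfit.fit_intensity(s, Vbar=vbar)
        else:
            aM = float(alpha.get(s.band, 1.0))
            fit = fluorfit.fit_anisotropy(s, aM, Vbar=vbar)
        results.append({"kind": s.kind, "band": s.band, "pH": s.pH,
                        "Kp": fit.Kp, "log10_Kp": fit.log10_Kp,
                        "endpoint_low": fit.endpoint_low,
                        "endpoint_high": fit.endpoint_high,
                        "alphaM": fit.alphaM, "stderr": fit.stderr,
                        "identifiable": fit.identifiable,
                        "residual_norm": fit.residual_norm})
    kps = [r["Kp"] for r in results if r["identifiable"]]
    agg = thermoagg.summarize_log_kp(kps).__dict__ if kps else None
    return {"fits": results, "log_kp_summary": agg}


def _fit_itc_workflow(cfg, params):
    proto = ITCProtocol(**cfg.params.get("protocol", {}))
    exp = read_itc_csv(cfg.inputs["heats"], proto)
    fit = itcfit.fit_itc(exp, Vbar=params["Vbar_L_per_mol"],
                         fit_q_dil=bool(cfg.params.get("fit_q_dil", False)),
                         drop_first=bool(cfg.params.get("drop_first", False)))
    dG = thermoagg.dG_from_kp(fit.Kp, proto.temperature)
    return {"Kp": fit.Kp, "dH_kJmol": fit.dH, "q_dil_J": fit.q_dil,
            "dG_kJmol": dG, "TdS_kJmol": thermoagg.tds_from(fit.dH, dG),
            "stderr": fit.stderr, "identifiable": fit.identifiable}


def _pmf_workflow(cfg, params, out_dir):
    windows = read_windows(cfg.inputs["windows"],
                           discard_frac=float(cfg.params.get("discard_frac", 0.0)))
    a = params["a_nm"]
    prof = pmfkit.bootstrap_pmf(
        windows, n_boot=int(cfg.params.get("n_boot", 50)), seed=cfg.seed,
        n_bins=int(params["wham_nbins"]), z_range=(0.0, a),
        T=params["T_K"], tol=params["wham_tol"],
        max_iter=int(params["wham_max_iter"]))
    write_pmf(out_dir / "pmf.txt", prof)
    summ = pmfkit.summarize_pmf(prof)
    return {"kp_rel": pmfkit.kp_from_pmf(prof, a),
            "summary": summ.__dict__, "pmf_file": "pmf.txt"}


def run_workflow(cfg: RunConfig) -> dict:
    """Run one workflow end to end; returns the report dict and writes it
    (plus stage outputs) under ``cfg.out_dir`` as ``report.json``.

    Deterministic given ``cfg.seed``; raises with the stage name on failure.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = dict(DEFAULTS)
    params.update({k: v for k, v in cfg.params.items() if k in DEFAULTS})
    try:
        if cfg.workflow == "fluor":
            payload = _fit_fluor_workflow(cfg, params)
        elif cfg.workflow == "itc":
            payload = _fit_itc_workflow(cfg, params)
        elif cfg.workflow == "pmf":
            payload = _pmf_workflow(cfg, params, out_dir)
        elif cfg.workflow == "simulate-fluor":
            truth = synthdata.FluorTruth(seed=cfg.seed,
                                         **cfg.params.get("truth", {}))
            series = [gen for band, aM in truth.alphaM_by_band.items()
                      for gen in (synthdata.gen_fluor_titration(
                          truth, kind="anisotropy", band=band),)]
            series.append(synthdata.gen_fluor_titration(truth, kind="intensity"))
            write_titration_csv(out_dir / "titrations.csv", series)
            payload = {"file": "titrations.csv", "truth_Kp": truth.Kp}
        elif cfg.workflow == "simulate-itc":
            proto = ITCProtocol(**cfg.params.get("protocol", {}))
            gen = cfg.params.get("gen", {})
            exp = synthdata.gen_itc_heats(
                proto, Kp=float(gen.get("Kp", 1e3)),
                dH=float(gen.get("dH", -50.0)),
                q_dil=float(gen.get("q_dil", 0.0)),
                noise_sd=float(gen.get("noise_sd", 0.0)), seed=cfg.seed)
            write_itc_csv(out_dir / "heats.csv", exp)
            payload = {"file": "heats.csv", "truth": gen}
        else:  # simulate-umbrella
            gen = dict(cfg.params.get("gen", {}))
            depth = float(gen.pop("well_depth_kJmol", -5.7))
            z0, z1 = gen.pop("well_range_nm", (1.0, 1.4))
            spec = synthdata.BrownianSpec(
                potential=_square_well(depth, z0, z1), seed=cfg.seed, **gen)
            meta = write_windows(out_dir, synthdata.gen_umbrella_windows(spec))
            payload = {"meta_file": meta.name, "well_depth_kJmol": depth}
    except Exception as err:
        raise RuntimeError(f"workflow {cfg.workflow!r} failed: {err}") from err

    report = {"workflow": cfg.workflow, "seed": cfg.seed,
              "defaults_applied": params, "result": payload}
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def _square_well(depth: float, z0: float, z1: float, width: float = 0.01):
    """Smoothed square well: depth inside [z0, z1], 0 outside, tanh edges."""
    def G(z):
        z = np.asarray(z, float)
        return depth * 0.25 * ((1 + np.tanh((z - z0) / width))
                               * (1 + np.tanh((z1 - z) / width)))
    return G
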