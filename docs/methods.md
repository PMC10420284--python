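# Methods

This note records the models implemented in `memparti`, the assumptions and
defaults behind them, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely open.

## Partition model and conventions

The solute distributes between water and a membrane pseudo-phase whose
volume is `Vbar * [lipid]`, with `Vbar = 0.8` L/mol (POPC molar volume).
`Kp` is the dimensionless concentration ratio for that convention; all free
energies labelled `dG = -RT ln Kp` inherit it. All lipid is assumed
accessible (full translocation between leaflets during equilibration); an
accessibility factor `gamma` in (0, 1] is exposed on the fluorescence fits
and defaults to 1. Temperature defaults to 298.15 K (25 °C, the calorimeter
bath) everywhere a temperature is needed; `R = 8.314` J/mol/K.

## Fluorescence fits

Both optical observables are two-endpoint saturation isotherms in
`x = Kp*Vbar*[L]`; the anisotropy isotherm is weighted by `aM` (the
membrane/water emission-intensity ratio in the detection band) because the
measured anisotropy is an intensity-weighted average of the two
environments. Note that only the product `aM*Kp` is identifiable from a
single anisotropy curve: an error in the assumed `aM` maps directly onto
`Kp`, which is why the joint multi-band fit (one shared `Kp`, per-band
endpoints) is the meaningful consistency check across detection bands.

`aM` can be estimated two ways, both implemented: the band-integral ratio of
the endpoint emission spectra (trapezoidal, band edges interpolated), or a
user-supplied value taken from the intensity trend.

Numerics: trust-region least squares (`scipy.optimize.least_squares`) over
`(log10 Kp, low, high)` with analytic Jacobian; the log parameterization
keeps `Kp` positive and matches the log-normal replicate statistics.
Multistart over three decades of `Kp` around a half-saturation heuristic
guards against local minima. Points are weighted uniformly by default
(per-point weights accepted). Degenerate inputs: a flat signal, or fitted
endpoints that coincide, set `identifiable = False` with a message rather
than raising; a singular Jacobian does the same. Fits require >= 3 distinct
lipid concentrations (the parameter count); a zero-lipid anchor is
recommended. Series are stored in ascending lipid order, making fits
trivially invariant to input point order.

## ITC partition model

Per-injection heats follow the perfusion-cell displacement recursion with
`d_i = (1 - v/V0)^i`: lipid in the cell rises as `L_syr*(1 - d_i)`, solute
dilutes as `D0*d_i`, the bound fraction is the same saturation isotherm as
above, and the heat of injection `i` is `dH` times the increment in bound
moles (with the previously bound moles scaled by one displacement step)
plus a constant per-injection dilution heat. The displacement correction is
applied to both solute and pre-existing lipid (the standard spreadsheet
convention for overfilled cells). Defaults: cell volume 1.4195 mL (VP-ITC
nominal), 25 x 10 uL injections, 10 mM lipid syringe, 5 uM solute. Heats
are joules internally; readers convert cal/mcal/ucal and mJ/uJ. Fitting is
least squares over `(log10 Kp, dH)` with optional `q_dil`; `drop_first`
excludes the first injection from the residuals while keeping it in the
displacement bookkeeping. A flat thermogram is flagged unidentifiable.
Incomplete inter-leaflet equilibration during a titration is a known caveat
of the uptake geometry and is not modelled.

## WHAM and the Boltzmann-integral Kp

Windows are histogrammed on a common grid (default 0.02 nm bins on
[0, 4] nm) and the unbiased bin probabilities solved self-consistently; the
implementation first minimizes the equivalent convex negative
log-likelihood in the window free energies (L-BFGS with analytic gradient)
and then iterates the self-consistent equations until
`max |delta ln f_j| < 1e-7` (configurable; max_iter 1e5), so the stated
convergence criterion is always the one actually met. Windows with no
samples in range are dropped; empty bins are masked (NaN). Adjacent windows
must share at least one populated bin or a `WindowOverlapError` names the
failing pair. Profiles are anchored so the mean over the outermost 0.5 nm
of populated bins (the bulk-water plateau) is zero; no symmetrization —
profiles are one-sided on [0, a].

Bin-width caveat: with stiff restraints (k = 3000 kJ/mol/nm², window
sigma = sqrt(RT/k) ≈ 0.029 nm) the bias varies steeply across a 0.02 nm
bin and produces a systematic over-deepening of order 0.1–0.3 kJ/mol. The
acceptance-scale umbrella analyses therefore use 0.005 nm bins; the package
default follows the common 0.02 nm choice and is configurable.

Uncertainty: bootstrap over whole windows (with replacement) combined with
a moving-block resample within each drawn window (block length default
n/20) to respect autocorrelation; every replicate profile is re-anchored
before the per-bin SD is taken, so the error estimate does not depend on
the anchoring convention. Convergence is diagnosed by recomputing the
profile on user-chosen time blocks with common binning and anchor.

`Kp_rel = (1/a) ∫_0^a exp(-dG/RT) dz` is evaluated by the trapezoid rule on
the bin-center grid extended to the exact [0, a] endpoints (a flat profile
gives exactly 1). The 1/a prefactor is a normalization convention: because
the anchor and the slab boundary `a = 4.0` nm are themselves conventions,
only log10 differences between profiles treated identically are
scientifically meaningful, and the implementation exposes exactly that
(`delta_log_kp`, exactly invariant to a common additive shift). Unpopulated
bins inside [0, a] raise a masked-gap error rather than silently
extrapolating.

Profile summaries report the global minimum, the maximum on the
bilayer-center side of it, their difference as the crossing barrier, and
the value at z = 0; a profile with no interior maximum is summarized to the
z = 0 value and flagged.

## Trajectory observables

Coordinates are nm, masses amu, densities kg/m³. Minimum image is applied
in x/y only; z is treated as unwrapped with the bilayer centered. Where a
bilayer species is present its per-frame COM defines z = 0; otherwise the
z = 0 plane is the reference. Observables are invariant under rigid
translation of each frame.

* Density: per-bin mass / (cross-section * bin width), frame-averaged; the
  profile integral equals the species mass per frame.
* Group positions: |z| is time-averaged per molecule first, then averaged
  across molecules with a t-based 95% CI (n = molecules), so the two
  leaflets pool and molecules are the unit of replication. Flagged
  molecules (e.g. aggregated pairs) are excluded via an explicit list, not
  automatic detection.
* Tilt: angle between the user-defined (tail -> head) axis and the outward
  normal of the molecule's leaflet, assigned per frame by the sign of the
  molecule COM relative to the bilayer COM; theta < 90° therefore always
  means "head toward water" in either leaflet. The axis atom pair is
  mandatory user input (it is a structural choice, not derivable from the
  data).
* Hydrogen bonds: donor-acceptor distance <= 0.35 nm and H-donor-acceptor
  angle <= 30°, the common MD-analysis default; both cutoffs are
  parameters so sensitivity can be reported. Entries are bonded-pair counts
  averaged over frames and donor molecules (mean bonds per frame per
  molecule, so entries may exceed 1); per-donor values divide the grand
  total by the number of donor groups, and acceptor-class fractions are
  percentages of the grand total.

## Synthetic worlds

The generators state a world once and the tests recover it; none of the
parameters below were tuned against test outcomes.

* Fluorescence: truth Kp = 1.8e3 (the pH 6 value), endpoints Iw = 1,
  Im = 10 a.u. and rw = 0.05, rm = 0.25 (chosen as realistic instrument
  values: strong intensity increase and marked anisotropy rise on membrane
  association; the source experiments print no endpoint numbers), band
  weightings aM = 13/8/5 for 450–470/470–490/490–510 nm. Noise is
  multiplicative Gaussian (CV), the natural model when intensities span
  orders of magnitude across bands. The titration grid is a 12-point
  geometric ladder over 1e-5–2e-3 M (the concentration axis of the source
  figures, which print no grid).
* ITC: additive Gaussian noise on heats; generating Kp values for the
  enthalpy-recovery worlds follow from the printed thermodynamics
  (dG = dH − TdS: −16 kJ/mol at pH 5.3 → Kp ≈ 636; −18 kJ/mol at
  pH 8.2 → Kp ≈ 1426).
* Umbrella windows: overdamped Euler–Maruyama dynamics on the 1-D reaction
  coordinate with the stated restraint ladder (41 centers, 0.1 nm apart,
  k = 3000 kJ/mol/nm²), RT at 298 K. Diffusion 1e-3 nm²/ps (small molecule
  in water), dt chosen so both the per-step RMS displacement (asserted
  < window spacing) and the discretization parameter D*dt*k/RT stay small;
  multiple independent chains per window pool into one sample set to reach
  adequate effective sample counts at desk scale. The square-well test
  world smooths the well edges with 0.02 nm tanh ramps so the force is
  bounded; the smoothed well's analytic Kp_rel is 1.85 vs 1.9 for the
  ideal sharp well.
* Toy trajectories: placements at fixed or Gaussian depths, long-axis
  orientations from a delta/Gaussian/uniform-sphere distribution, and
  H-bond geometries switched on in an exactly prescribed fraction of frames
  (Bresenham alternation, so occupancies are exact rather than
  statistical). These fixtures have known statistics by construction; a
  green recovery test establishes that the observables are computed
  correctly, not that real bilayer MD would produce those values. The 1-D
  Brownian generator likewise exercises WHAM, not membrane physics: there
  is no force field, no lipid degrees of freedom, and no
  orientation/position coupling.

## Known limitations

* No MBAR, 2-D PMFs, or permeability (solubility–diffusion) estimates; the
  PMF route stops at relative Kp.
* No raw ITC power-trace integration, binding-stoichiometry models, or
  buffer-ionization corrections.
* No spectral deconvolution or scatter/inner-filter corrections on the
  optical route; single-site partition only.
* Trajectory readers handle multi-frame GRO and a plain XYZ-with-box
  dialect only; compressed binary formats are out of scope.
* Absolute Kp from a PMF is out of reach by construction (reference-state
  and boundary conventions); the implementation deliberately reports
  relative values only.
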