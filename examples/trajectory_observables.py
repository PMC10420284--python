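"""Bilayer trajectory observables on a constructed toy system.

Builds a trajectory in which every statistic is known by construction — an
ethoxy-like oxygen placed at depth N(0.89, 0.21) nm, a solute long axis
tilted 52 deg from the outward leaflet normal, and N-H...O hydrogen bonds
switched on in exactly half of the frames — and recovers each with the
trajectory toolkit.
"""

import memparti as mp
from memparti.synthdata import HBondPairSpec, Placement, ToyTrajSpec

spec = ToyTrajSpec(
    placements=(Placement("O41", 16.0, "solute", ("gaussian", 0.89, 0.21)),),
    n_molecules=12, n_frames=400,
    axis_angle_dist=("delta", 52.0),
    hbond_pairs=(HBondPairSpec("N2", "HN2", "O16", 0.5),),
    seed=4)
traj = mp.gen_toy_trajectory(spec)

tab = mp.group_positions(traj, {"O41": ["O41"]}, list(range(12)),
                         bilayer_species=None)
row = tab.loc["O41"]
print(f"O41 depth: {row.mean_abs_z_nm:.2f} +/- {row.ci_half_width_nm:.2f} nm "
      f"(95% CI over 12 molecules; truth 0.89)")

tilt = mp.tilt_distribution(traj, ("TAIL", "HEAD"), list(range(12)),
                            bilayer_species=None)
print(f"mean long-axis tilt: {tilt.mean_theta:.1f} deg "
      f"(< 90 deg: head group points toward water)")

hb = mp.hbond_frequencies(traj, [("N2", "HN2")], {"carbonyl": ["O16"]})
print(f"N2-H...carbonyl H-bond fractional frequency: "
      f"{hb.freq.loc['N2', 'carbonyl']:.3f} (constructed 0.500)")
print(f"per donor: {mp.per_donor_frequency(hb):.2f}")

dens = mp.mass_density_profile(traj, "solute", bin_width=0.1,
                               bilayer_species=None)
peak = dens.z_centers[dens.density.argmax()]
print(f"solute density peak at z = {peak:.2f} nm")
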