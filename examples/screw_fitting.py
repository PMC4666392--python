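"""Fit the filament screw symmetry from coordinates.

A screw transform (rotation about + translation along one axis) generates
the filament: fitting it between equivalent regions recovers the helical
parameters, here demonstrated on the protein scaffold frames.
"""

import numpy as np

import filamentforge as ff

scaffold = ff.make_scaffold_anchor_frames(6)
fit = ff.fit_screw(scaffold.select(residues=[1]).coords,
                   scaffold.select(residues=[2]).coords)
print(f"monomer-to-monomer screw: {fit.angle_per_step:.2f} deg, "
      f"{fit.translation_per_step:.2f} A along axis {np.round(fit.axis_dir, 3)}")
print(f"subunits per turn: {360.0 / fit.angle_per_step:.2f}")

# Replicating a trinucleotide by that screw builds one helical turn of
# filament DNA: 6 subunits x 3 nt = 18 nt.
tri = ff.build_filament_strand("TTT")
turn = ff.replicate_along_screw(tri, fit, 6)
axis = ff.infer_axis(turn, period=3)
print(f"replicated strand: {len(turn.residue_indices('A'))} nt, "
      f"axis direction {np.round(axis.direction, 6)}")
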