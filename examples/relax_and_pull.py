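"""Spring-network refinement: backbone closure and the radial pull.

Replicated trinucleotide fragments are linked into one continuous strand
under phosphate restraints, and a strand built at 12 A is pulled to the
favorable 15 A site-II radius without disturbing its screw symmetry.
"""

import numpy as np

import filamentforge as ff
from filamentforge import springs

# -- closure of screw-replicated fragments ----------------------------------
tri = ff.build_filament_strand("TTT")
tri.atom("A", 3, "O3'").position += np.array([0.0, 0.0, 0.8])   # open the seams
screw = ff.ScrewTransform(np.zeros(3), [0, 0, 1], 60.0, 15.3)
fragments = [ff.apply_screw(screw, tri, k) for k in range(6)]
closed = springs.close_backbone(fragments, screw)
bonds = [np.linalg.norm(closed.atom("A", r, "O3'").position
                        - closed.atom("A", r + 1, "P").position)
         for r in range(3, 18, 3)]
print(f"closed strand: {len(closed.residue_indices('A'))} nt, junction O3'-P "
      f"bonds {min(bonds):.2f}-{max(bonds):.2f} A (target 1.6)")

# -- radial pull under constant helical symmetry ----------------------------
strand = ff.build_filament_strand("T" * 9, ff.HelicalParams(radius=12.0))
pulled = springs.radial_pull(strand, [1, 2, 4, 5, 7, 8], 15.0)
axis = ff.Axis(np.zeros(3), [0, 0, 1])
radii = axis.radii(pulled.atom_positions("A", "P", [1, 2, 4, 5, 7, 8]))
fit = ff.fit_screw(pulled.select(residues=[1, 2, 3]).coords,
                   pulled.select(residues=[4, 5, 6]).coords)
print(f"pulled phosphate radius {radii.mean():.2f} A (target 15); "
      f"triplet screw after pull: {fit.angle_per_step:.2f} deg, "
      f"{fit.translation_per_step:.2f} A")
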