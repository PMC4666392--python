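"""The duplet flip: the elementary homology-sampling move.

Two stacked complementary bases of a site-II triplet swing toward the
initiating strand; the D1/theta1 base-pairing metrics classify each pair
before and after, and the salt-bridge map shows the protein contact that
the move releases.
"""

import filamentforge as ff
from filamentforge import anchors as anc
from filamentforge import metrics

model = ff.build_synaptic_model("T" * 20, ff.TripletPattern(2, 6, 6))
site2 = anc.generate_siteII_anchors(anc.filament_screw(), 4)

flipped = ff.flip_duplet(ff.flip_duplet(model, 1), 2)
print("pair   D1 before -> after   state")
for before, after in zip(metrics.all_basepair_metrics(model),
                         metrics.all_basepair_metrics(flipped)):
    print(f"  {before.pair_index}    {before.D1:5.1f} A  -> {after.D1:5.1f} A   "
          f"{after.state}")

lost = ({(c.phosphate, c.label) for c in anc.salt_bridge_map(model, site2)}
        - {(c.phosphate, c.label) for c in anc.salt_bridge_map(flipped, site2)})
print(f"salt bridges released by the flips: {sorted(lost)}")
# D1 = 10.4 A is the paired C1'-C1' distance of the package's own B-form
# template; the 3' base of each triplet stays unflipped (D1 = 21 A).
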