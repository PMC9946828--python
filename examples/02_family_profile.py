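"""Build family-wide geometry restraints from a synthetic family.

Generates a 6-member toy family (helix - variable loop - strand) whose
members share conserved segments but differ in loop length, classifies
the alignment columns into conserved vs variable regions, and pools
the binned inter-residue geometries into a restraint profile.
"""

import numpy as np

from famhal.family import build_profile, classify_regions
from famhal.fixtures import ToyFamilySpec, make_toy_family

spec = ToyFamilySpec()  # helix(10) + loop(2..4) + strand(8), 6 members
family = make_toy_family(spec)

print("alignment:")
for m, row in enumerate(family.alignment):
    print(f"  member{m}  {row}")

annotation = classify_regions(family.alignment, gap_threshold=0.0,
                              min_segment_length=3)
print(f"\nconserved segments (columns): {annotation.conserved_segments}")
print(f"variable segments  (columns): {annotation.variable_segments}")
print(f"loop length bounds          : {annotation.loop_length_bounds}")

profile = build_profile(family.structures, family.alignment,
                        family.annotation)
support = profile.support
d = profile.restraints["d"]
print(f"\nprofile: {profile.n_pairs} conserved-column pairs")
print(f"support per pair            : min {support.min()}, max {support.max()}")
print(f"mean occupied distance bins : "
      f"{(d > d.min(axis=1, keepdims=True)).sum(axis=1).mean():.1f} of {d.shape[1]}")
print()
print("Each pair carries one categorical distribution per geometry channel")
print("(distance d, dihedrals omega/theta, planar angle phi); loop-length")
print("variation across members spreads the inter-segment distributions.")
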