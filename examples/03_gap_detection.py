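"""Detect, merge and stratify junctional gaps; associate AJ with TJ.

Uses the late-stage adhesion-mutant preset, in which gaps concentrate
at higher-order junctions.
"""

from junctionscope import (RegionSpec, associate_aj_tj, detect_gaps,
                           estimate_background, generate_field,
                           merge_overlapping_gaps, preset,
                           region_gap_count, stratify_gap_frequency)

field = generate_field(preset("mutant_late"), seed=3, channels=("aj", "tj"))
bg = estimate_background(field.channels["aj"], field.graph, seed=3)

aj = merge_overlapping_gaps(
    detect_gaps(field.channels["aj"], field.graph, bg.value))
tj = merge_overlapping_gaps(
    detect_gaps(field.channels["tj"], field.graph, bg.value, channel="TJ"))
_, assoc = associate_aj_tj(aj, tj)

region = RegionSpec((5, 5), (50, 50))
strat = stratify_gap_frequency(aj, field.graph, region)

print("gaps in 50x50 um region:", region_gap_count(aj, region))
print("fraction of junctions gapped, by order:",
      {k: round(strat[k], 2) for k in ("3", "4", "5+")})
print(f"AJ gaps with a TJ gap: {assoc['n_associated']}/{assoc['n_aj']} "
      f"({assoc['n_unassociated']} unassociated)")
# Gap frequency rises steeply with junction order (the highest-tension
# sites); only a minority of AJ gaps have a corresponding TJ gap.
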