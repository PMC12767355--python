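"""Planar polarity and tricellular enrichment from a rendered channel.

Renders a field with 1.5-fold mediolateral polarity and 1.5-fold TCJ
enrichment, then recovers both from the image alone.
"""

import numpy as np

from junctionscope import (estimate_background, generate_field,
                           planar_polarity, preset, tcj_ratio)

field = generate_field(preset("control_late", gap_prob_by_order={}), seed=2)
img = field.channels["aj"]
bg = estimate_background(img, field.graph, seed=2)
pol = planar_polarity(img, field.graph, None, bg.value)

ratios = []
for vid in field.graph.vertices.query("order == 3")["id"]:
    try:
        ratios.append(tcj_ratio(img, field.graph, int(vid), bg.value).ratio)
    except ValueError:          # edge too short to sample cleanly
        continue

print(f"background: {bg.value:.1f} a.u. from {bg.n_rois} cytoplasmic ROIs")
print(f"ML/AP polarity ratio: {pol.ratio:.3f} "
      f"({pol.n_ml} ML edges, {pol.n_ap} AP edges)")
print(f"mean TCJ enrichment: {np.mean(ratios):.3f} over {len(ratios)} vertices")
# Both ratios recover the configured 1.5 within noise: the polarity is
# the ML/AP intensity contrast, the TCJ ratio the vertex enrichment over
# its three bicellular edges.
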