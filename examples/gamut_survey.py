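"""Map the attainable quasi-color gamut over the pigment domain.

A dense grid over SR-S in [0, 9.7] and Lb-A in [0, 8.0] enumerates every
quasi-color the published model can produce, then summarizes slices and
corners of that gamut.
"""

from cmqleaf import PigmentGrid, attainable_range, compute_gamut, hue_extremes, published_cmq_network

net = published_cmq_network()
table = compute_gamut(net, PigmentGrid(step=0.1))
print(f"gamut table: {len(table)} grid points")

lo, hi = attainable_range(table, "qb", "srs", 5.0)
print(f"attainable qb* at SR-S = 5.0: {lo:.1f} .. {hi:.1f}")
lo, hi = attainable_range(table, "qb", "lba", 4.0)
print(f"attainable qb* at Lb-A = 4.0: {lo:.1f} .. {hi:.1f}")

corners = hue_extremes(table)
print(
    f"anthocyanin-only corner hue: {corners['anthocyanin_corner_hue']:.0f} deg "
    "(purple-red)"
)
print(
    f"chlorophyll-only corner hue: {corners['chlorophyll_corner_hue']:.0f} deg (green)"
)
peak = table.loc[table.qC.idxmax()]
print(
    f"most vivid quasi-color (qC*={peak.qC:.1f}) at SR-S={peak.srs:.1f}, "
    f"Lb-A={peak.lba:.1f}"
)

# Anthocyanins constrain qb* tightly while chlorophylls barely do; the most
# vivid quasi-colors occur when a single pigment dominates, never when both
# are abundant together.
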