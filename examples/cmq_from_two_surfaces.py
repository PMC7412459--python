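"""Compute the CMQ and surface color difference from two measured surfaces.

The pair below is the most dorsiventrally extreme leaf of the original
survey: a very dark red adaxial surface over a green abaxial surface.
"""

from cmqleaf import LeafColorPair, SurfaceColor, compute_cmq

pair = LeafColorPair(
    adaxial=SurfaceColor(L=26.2, a=8.0, b=-9.9),
    abaxial=SurfaceColor(L=44.0, a=-12.0, b=28.0),
)
cmq = compute_cmq(pair)

print(f"adaxial  chroma {pair.adaxial.C:5.1f}, hue {pair.adaxial.h():5.0f} deg")
print(f"abaxial  chroma {pair.abaxial.C:5.1f}, hue {pair.abaxial.h():5.0f} deg")
print(f"deltaE between surfaces: {pair.delta_e:.1f}")
print(f"CMQ: qL*={cmq.qL:.2f} qa*={cmq.qa:.2f} qb*={cmq.qb:.2f}")

# A surface-to-surface deltaE of 46.4 is far above the survey mean of ~10,
# showing why a single-surface color cannot represent this leaf; the CMQ
# midpoint is the quantity that tracks its total pigment content.
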