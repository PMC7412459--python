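"""Estimate the color of an unobserved leaf surface.

If pigments are known and one surface has been measured, the other surface
follows from the CMQ midpoint identity: hidden = 2 * CMQ - known.  The case
below is lettuce sample LS-101, whose abaxial side was actually measured at
(50.3, -4.1, 16.3) — close to the estimate.
"""

from cmqleaf import PigmentLevel, SurfaceColor, estimate_hidden_surface

adaxial = SurfaceColor(L=23.1, a=8.1, b=5.2)
estimate = estimate_hidden_surface(adaxial, PigmentLevel(srs=5.4, lba=3.9))

print(f"measured adaxial:   L*={adaxial.L:.1f} a*={adaxial.a:.1f} b*={adaxial.b:.1f}")
print(
    f"estimated abaxial:  L*={estimate.L:.1f} a*={estimate.a:.1f} b*={estimate.b:.1f}"
    f"  (lightness in range: {estimate.lightness_in_range})"
)
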