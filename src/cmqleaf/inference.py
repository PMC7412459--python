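"""Inferring the color of the unobserved leaf surface.

The CMQ is the per-axis mean of the two surface colors, so once the CMQ is
predicted from pigment content, the hidden surface follows from the observed
one by reflection through the midpoint: hidden = 2 * CMQ - known.  The
relation is symmetric — it does not matter which surface was measured — and
involutive: reflecting the estimate recovers the original measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .colorimetry import CMQCoordinates, SurfaceColor, chroma, hue_angle
from .network import TanhNetwork, predict_cmq, published_cmq_network
from .pigments import PigmentLevel

__all__ = ["EstimatedSurface", "estimate_hidden_surface"]


@dataclass(frozen=True)
class EstimatedSurface:
    """Model-estimated CIELab triple for an unobserved surface.

    Unlike a measured :class:`~cmqleaf.colorimetry.SurfaceColor`, the
    estimate is allowed to leave the physical lightness range; the
    ``lightness_in_range`` flag records whether it did.  Values are never
    clipped.
    """

    L: float
    a: float
    b: float

    @property
    def lightness_in_range(self) -> bool:
        return 0.0 <= self.L <= 100.0

    @property
    def C(self) -> float:
        return chroma(self.a, self.b)

    def h(self, scale: str = "0-360") -> float:
        return hue_angle(self.a, self.b, scale=scale)

    def as_surface_color(self) -> SurfaceColor:
        """Validated surface color; raises if lightness is out of range."""
        return SurfaceColor(self.L, self.a, self.b)


def estimate_hidden_surface(
    known: SurfaceColor,
    pigments: PigmentLevel,
    net: TanhNetwork = None,
) -> EstimatedSurface:
    """Estimate the unobserved surface as 2 * predicted CMQ - known surface.

    ``known`` may be either surface; by symmetry of the midpoint the same
    formula applies.  Uses the published network when ``net`` is omitted.
    By construction the midpoint of (known, estimate) equals the predicted
    CMQ exactly.
    """
    if net is None:
        net = published_cmq_network()
    cmq: CMQCoordinates = predict_cmq(net, pigments)
    return EstimatedSurface(
        L=2.0 * cmq.qL - known.L,
        a=2.0 * cmq.qa - known.a,
        b=2.0 * cmq.qb - known.b,
    )
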