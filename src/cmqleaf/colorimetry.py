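"""CIELab arithmetic for bifacial leaves.

Leaf color is recorded as CIELab triples (L*, a*, b*) on the adaxial (upper)
and abaxial (lower) surface at antipodal points.  The conceptual midpoint
quasi-color (CMQ) combines the two surfaces into a single notional color whose
coordinates are the per-axis means of the two measurements.  The CMQ is not a
color anyone can see on the leaf; it is the quantity that tracks total pigment
content when the two surfaces differ.

Hue angles are handled on two scales.  The conventional CIELab scale is
[0, 360).  For statistics, angles above 180 deg are shifted by -360 so that
the purple-red hues that straddle 0/360 average correctly ("wrapped" scale,
(-180, 180]).  The 180 deg threshold is safe for leaves: cyan/teal hues do
not occur in foliage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "SurfaceColor",
    "LeafColorPair",
    "CMQCoordinates",
    "UndefinedHueError",
    "chroma",
    "hue_angle",
    "wrap_hue",
    "unwrap_hue",
    "delta_e",
    "compute_cmq",
]


class UndefinedHueError(ValueError):
    """Hue angle is undefined at the achromatic point a = b = 0."""


def chroma(a: float, b: float) -> float:
    """Chroma C* = sqrt(a*^2 + b*^2); the vividness of the color."""
    return math.hypot(a, b)


def hue_angle(a: float, b: float, scale: str = "0-360") -> float:
    """Hue angle of (a*, b*) in degrees, quadrant-aware.

    Parameters
    ----------
    a, b
        CIELab chromatic coordinates; must not both be zero.
    scale
        ``"0-360"`` for the conventional [0, 360) scale or ``"wrapped"``
        for the statistics-friendly (-180, 180] scale.
    """
    if a == 0.0 and b == 0.0:
        raise UndefinedHueError("hue angle undefined at a = b = 0")
    h = math.degrees(math.atan2(b, a)) % 360.0
    if scale == "0-360":
        return h
    if scale == "wrapped":
        return wrap_hue(h)
    raise ValueError(f"unknown hue scale {scale!r}; use '0-360' or 'wrapped'")


def wrap_hue(h: float) -> float:
    """Map a hue on [0, 360) to the wrapped (-180, 180] scale.

    Angles strictly above 180 deg are shifted by -360 so hues near the red
    0/360 boundary average correctly; 180 itself is kept (half-open
    convention — no leaf hues occur there).
    """
    if not 0.0 <= h < 360.0:
        raise ValueError(f"hue {h} outside [0, 360)")
    return h if h <= 180.0 else h - 360.0


def unwrap_hue(h: float) -> float:
    """Exact inverse of :func:`wrap_hue`: (-180, 180] back to [0, 360)."""
    if not -180.0 < h <= 180.0:
        raise ValueError(f"wrapped hue {h} outside (-180, 180]")
    if h >= 0.0:
        return h
    res = h + 360.0
    # tiny negative hues can round up to 360.0, which is outside [0, 360)
    return res if res < 360.0 else 0.0


@dataclass(frozen=True)
class SurfaceColor:
    """CIELab color of one leaf surface.

    L is lightness on [0, 100] (0 = black, 100 = white); a is the red (+) /
    green (-) axis; b is the yellow (+) / blue (-) axis.
    """

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.L, self.a, self.b))):
            raise ValueError("CIELab coordinates must be finite")
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L* = {self.L} outside [0, 100]")

    @property
    def C(self) -> float:
        return chroma(self.a, self.b)

    def h(self, scale: str = "0-360") -> float:
        return hue_angle(self.a, self.b, scale=scale)

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class LeafColorPair:
    """Colors at antipodal adaxial/abaxial points of one leaf spot."""

    adaxial: SurfaceColor
    abaxial: SurfaceColor

    @property
    def delta_e(self) -> float:
        """Surface-to-surface color difference ΔE_DB."""
        return delta_e(self.adaxial, self.abaxial)


@dataclass(frozen=True)
class CMQCoordinates:
    """Conceptual midpoint quasi-color: per-axis mean of the two surfaces.

    qL may exceed the [0, 100] lightness range when produced by a model
    extrapolating outside its calibration; unlike a measured surface color
    it is therefore not range-validated.
    """

    qL: float
    qa: float
    qb: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.qL, self.qa, self.qb))):
            raise ValueError("CMQ coordinates must be finite")

    @property
    def qC(self) -> float:
        return chroma(self.qa, self.qb)

    def qh(self, scale: str = "0-360") -> float:
        return hue_angle(self.qa, self.qb, scale=scale)

    def as_array(self) -> np.ndarray:
        return np.array([self.qL, self.qa, self.qb], dtype=float)


ColorLike = Union[SurfaceColor, CMQCoordinates, "np.ndarray", tuple, list]


def _triple(c: ColorLike) -> np.ndarray:
    if isinstance(c, (SurfaceColor, CMQCoordinates)):
        return c.as_array()
    arr = np.asarray(c, dtype=float)
    if arr.shape != (3,):
        raise ValueError("expected a 3-coordinate color triple")
    return arr


def delta_e(c1: ColorLike, c2: ColorLike) -> float:
    """Euclidean CIELab color difference ΔE = sqrt(ΔL² + Δa² + Δb²).

    Accepts surface colors, CMQ coordinates, or plain 3-sequences; applying
    it between quasi-colors (ΔqE) treats the CMQ triple as an ordinary
    CIELab point, which is how model-vs-observation differences are scored.
    """
    t1, t2 = _triple(c1), _triple(c2)
    if not (np.isfinite(t1).all() and np.isfinite(t2).all()):
        raise ValueError("color triples must be finite")
    return float(np.linalg.norm(t1 - t2))


def compute_cmq(pair: LeafColorPair) -> CMQCoordinates:
    """CMQ of a leaf spot: the exact midpoint of the two surface colors."""
    d, b = pair.adaxial, pair.abaxial
    return CMQCoordinates(
        qL=(d.L + b.L) / 2.0,
        qa=(d.a + b.a) / 2.0,
        qb=(d.b + b.b) / 2.0,
    )
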