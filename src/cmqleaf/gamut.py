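"""Attainable quasi-color gamut over pigment grids.

Evaluating the network on a dense (SR-S, Lb-A) grid enumerates every
quasi-color the model can produce — the gamut.  The resulting table supports
range queries (which qb* values are attainable at a given chlorophyll
level?), corner summaries (hue when only one pigment is abundant), and
sum/difference views of combined pigment load.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colorimetry import unwrap_hue
from .network import TanhNetwork, predict_cmq_batch

__all__ = [
    "PigmentGrid",
    "compute_gamut",
    "attainable_range",
    "hue_extremes",
    "render_heatmap",
]


@dataclass(frozen=True)
class PigmentGrid:
    """Regular grid over the calibrated pigment domain (step in both axes)."""

    srs_range: tuple = (0.0, 9.7)
    lba_range: tuple = (0.0, 8.0)
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        for name, (lo, hi) in (("srs", self.srs_range), ("lba", self.lba_range)):
            if hi < lo:
                raise ValueError(f"{name} range {(lo, hi)} is reversed")

    def _axis(self, lo: float, hi: float) -> np.ndarray:
        n = int(round((hi - lo) / self.step)) + 1
        pts = lo + self.step * np.arange(n)
        return np.round(pts[pts <= hi + 1e-9], 10)

    @property
    def srs_points(self) -> np.ndarray:
        return self._axis(*self.srs_range)

    @property
    def lba_points(self) -> np.ndarray:
        return self._axis(*self.lba_range)


def compute_gamut(net: TanhNetwork, grid: PigmentGrid = PigmentGrid()) -> pd.DataFrame:
    """Predict the quasi-color at every grid point.

    Returns one row per (srs, lba) combination with columns qL, qa, qb, the
    derived chroma qC, hue on both scales (qh on [0, 360), qh_wrapped on
    (-180, 180]), and the pigment sum/difference views srs_plus_lba and
    srs_minus_lba.
    """
    S, A = np.meshgrid(grid.srs_points, grid.lba_points, indexing="ij")
    srs, lba = S.ravel(), A.ravel()
    Y = predict_cmq_batch(net, srs, lba)
    qa, qb = Y[:, 1], Y[:, 2]
    qh = np.degrees(np.arctan2(qb, qa)) % 360.0
    table = pd.DataFrame(
        {
            "srs": srs,
            "lba": lba,
            "qL": Y[:, 0],
            "qa": qa,
            "qb": qb,
            "qC": np.hypot(qa, qb),
            "qh": qh,
            "qh_wrapped": np.where(qh <= 180.0, qh, qh - 360.0),
            "srs_plus_lba": srs + lba,
            "srs_minus_lba": srs - lba,
        }
    )
    return table


def attainable_range(
    table: pd.DataFrame, coordinate: str, fixed_input: str, fixed_value: float
) -> tuple:
    """(min, max) of one coordinate over the grid slice fixing one pigment."""
    if coordinate not in table.columns:
        raise KeyError(f"unknown coordinate {coordinate!r}")
    if fixed_input not in ("srs", "lba"):
        raise ValueError("fixed_input must be 'srs' or 'lba'")
    mask = np.isclose(table[fixed_input].to_numpy(), fixed_value, atol=1e-9)
    if not mask.any():
        raise ValueError(f"{fixed_input} = {fixed_value} is not on the grid")
    vals = table.loc[mask, coordinate]
    return float(vals.min()), float(vals.max())


def hue_extremes(table: pd.DataFrame, corner_fraction: float = 0.1) -> dict:
    """Mean hue in the single-pigment corners of the gamut.

    The anthocyanin-only corner is the top ``corner_fraction`` of the lba
    axis crossed with the bottom fraction of the srs axis (and vice versa
    for chlorophyll-only).  Hues are averaged on the wrapped scale — the
    anthocyanin corner sits near the 0/360 boundary — and reported on the
    conventional [0, 360) scale.
    """
    if table.empty:
        raise ValueError("empty gamut table")
    s_lo, s_hi = table["srs"].min(), table["srs"].max()
    a_lo, a_hi = table["lba"].min(), table["lba"].max()
    s_cut = s_lo + corner_fraction * (s_hi - s_lo)
    s_top = s_hi - corner_fraction * (s_hi - s_lo)
    a_cut = a_lo + corner_fraction * (a_hi - a_lo)
    a_top = a_hi - corner_fraction * (a_hi - a_lo)

    anth = table[(table["srs"] <= s_cut) & (table["lba"] >= a_top)]
    chlo = table[(table["srs"] >= s_top) & (table["lba"] <= a_cut)]
    if anth.empty or chlo.empty:
        raise ValueError("gamut table does not cover the corner regions")

    def corner_mean(sub: pd.DataFrame) -> float:
        mean_wrapped = float(sub["qh_wrapped"].mean())
        # mean of wrapped hues can land exactly on a bound; nudge into domain
        mean_wrapped = min(max(mean_wrapped, np.nextafter(-180.0, 0.0)), 180.0)
        return unwrap_hue(mean_wrapped)

    return {
        "anthocyanin_corner_hue": corner_mean(anth),
        "chlorophyll_corner_hue": corner_mean(chlo),
    }


def render_heatmap(table: pd.DataFrame, coordinate: str, path) -> None:
    """Render one coordinate of the gamut as an srs × lba heat map image.

    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if coordinate not in table.columns:
        raise KeyError(f"unknown coordinate {coordinate!r}")
    pivot = table.pivot(index="lba", columns="srs", values=coordinate)
    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(pivot.columns, pivot.index, pivot.to_numpy(), shading="auto")
    fig.colorbar(mesh, ax=ax, label=coordinate)
    ax.set_xlabel("SR-S (chlorophylls)")
    ax.set_ylabel("Lb-A (anthocyanins)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
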