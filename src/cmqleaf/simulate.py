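"""Synthetic leaf datasets with the lettuce survey's summary structure.

The generator emulates the statistical shape of a large single-species leaf
survey: chlorophyll levels (SR-S) spanning 0-8.6 with mean 5.8, anthocyanin
levels (Lb-A) spanning 0.1-7.8 with mean 3.6, quasi-color observations
scattered around the published network's surface, and a dorsiventral color
asymmetry averaging ΔE ≈ 10.3 between the two surfaces.

Construction per leaf:

1. pigments drawn from truncated normal marginals (optionally correlated via
   a Gaussian copula); the location parameter of each truncated normal is
   solved numerically so the *realized* mean equals the configured target;
2. true CMQ = published-network prediction at the drawn pigments;
3. observed CMQ = true CMQ + independent Gaussian noise per coordinate;
4. the two surfaces are placed symmetrically about the observed CMQ along a
   uniformly random direction in (L, a, b) space, oriented so the adaxial
   surface is the darker one, with surface-to-surface ΔE drawn from an
   exponential distribution (heavy right tail) with the configured mean.

By construction the midpoint of the two surfaces reproduces the observed
CMQ exactly, so the generated records are internally consistent for
training, evaluation, and surface-inference testing alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .colorimetry import CMQCoordinates
from .network import TanhNetwork, predict_cmq_batch, published_cmq_network
from .pigments import PigmentLevel
from .training import TrainingSample

__all__ = [
    "GeneratorConfig",
    "generate_leaf_samples",
    "dataset_summary",
    "samples_from_frame",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic leaf generator.

    Defaults reproduce the primary survey's reported summaries: pigment
    ranges and means, per-coordinate observation noise equal to the
    network's training-set RMSE (1.81 / 1.23 / 1.71 for qL / qa / qb), and
    a mean surface-to-surface color difference of 10.3 ΔE units.
    """

    n: int = 604
    srs_mean: float = 5.8
    srs_range: tuple = (0.0, 8.6)
    lba_mean: float = 3.6
    lba_range: tuple = (0.1, 7.8)
    srs_sd: float = None  # default (range width)/4
    lba_sd: float = None
    noise_sd: tuple = (1.81, 1.23, 1.71)
    asymmetry_mean_delta_e: float = 10.3
    pigment_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if any(s < 0 for s in self.noise_sd) or len(self.noise_sd) != 3:
            raise ValueError("noise_sd must be three non-negative values")
        if self.asymmetry_mean_delta_e < 0:
            raise ValueError("asymmetry_mean_delta_e must be non-negative")
        if not -1.0 < self.pigment_correlation < 1.0:
            raise ValueError("pigment_correlation must lie in (-1, 1)")
        for name, (lo, hi) in (("srs", self.srs_range), ("lba", self.lba_range)):
            if not hi > lo:
                raise ValueError(f"degenerate {name} range {(lo, hi)}")
        if self.srs_sd is None:
            object.__setattr__(self, "srs_sd", (self.srs_range[1] - self.srs_range[0]) / 4)
        if self.lba_sd is None:
            object.__setattr__(self, "lba_sd", (self.lba_range[1] - self.lba_range[0]) / 4)
        for name, sd in (("srs_sd", self.srs_sd), ("lba_sd", self.lba_sd)):
            if sd <= 0:
                raise ValueError(f"{name} must be positive")


def _centered_truncnorm(target_mean: float, sd: float, lo: float, hi: float):
    """Truncated normal on [lo, hi] whose mean equals ``target_mean``.

    Asymmetric truncation shifts the mean away from the location parameter,
    so the location is solved for rather than set to the target.
    """
    if not lo < target_mean < hi:
        raise ValueError(f"target mean {target_mean} outside ({lo}, {hi})")

    def mean_gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    lo_loc, hi_loc = lo - 10 * sd, hi + 10 * sd
    loc = optimize.brentq(mean_gap, lo_loc, hi_loc, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm(a, b, loc=loc, scale=sd)


def generate_leaf_samples(
    config: GeneratorConfig = GeneratorConfig(), net: TanhNetwork = None
) -> pd.DataFrame:
    """Generate ``config.n`` synthetic leaf records.

    Returns a data frame with one row per leaf: pigments (srs, lba), the
    noise-free network prediction (true_qL/qa/qb), the noisy observation
    (qL/qa/qb), and the two surface colors (L_D, a_D, b_D / L_B, a_B, b_B)
    whose midpoint equals the noisy observation exactly.
    """
    if net is None:
        net = published_cmq_network()
    rng = np.random.default_rng(config.seed)
    n = config.n

    srs_dist = _centered_truncnorm(config.srs_mean, config.srs_sd, *config.srs_range)
    lba_dist = _centered_truncnorm(config.lba_mean, config.lba_sd, *config.lba_range)
    rho = config.pigment_correlation
    if rho == 0.0:
        srs = srs_dist.ppf(rng.uniform(size=n))
        lba = lba_dist.ppf(rng.uniform(size=n))
    else:
        # Gaussian copula: correlated normal scores, truncated-normal margins
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal(np.zeros(2), cov, size=n)
        srs = srs_dist.ppf(stats.norm.cdf(z[:, 0]))
        lba = lba_dist.ppf(stats.norm.cdf(z[:, 1]))

    true = predict_cmq_batch(net, srs, lba)
    observed = true + rng.normal(0.0, config.noise_sd, size=(n, 3))

    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    # adaxial surfaces read darker on average; orient the split accordingly
    direction[direction[:, 0] < 0] *= -1.0
    magnitude = rng.exponential(config.asymmetry_mean_delta_e, size=n)
    half = 0.5 * magnitude[:, None] * direction
    adaxial = observed - half
    abaxial = observed + half

    return pd.DataFrame(
        {
            "sample_id": [f"SYN-{i + 1:04d}" for i in range(n)],
            "srs": srs,
            "lba": lba,
            "true_qL": true[:, 0],
            "true_qa": true[:, 1],
            "true_qb": true[:, 2],
            "qL": observed[:, 0],
            "qa": observed[:, 1],
            "qb": observed[:, 2],
            "L_D": adaxial[:, 0],
            "a_D": adaxial[:, 1],
            "b_D": adaxial[:, 2],
            "L_B": abaxial[:, 0],
            "a_B": abaxial[:, 1],
            "b_B": abaxial[:, 2],
        }
    )


def dataset_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Min / mean / max per column plus the surface-to-surface ΔE summary."""
    if len(records) == 0:
        raise ValueError("empty record set")
    cols = [
        c
        for c in ("srs", "lba", "qL", "qa", "qb", "L_D", "L_B")
        if c in records.columns
    ]
    if not cols:
        raise ValueError("records contain none of the expected columns")
    summary = records[cols].agg(["min", "mean", "max"]).T
    surface_cols = ["L_D", "a_D", "b_D", "L_B", "a_B", "b_B"]
    if all(c in records.columns for c in surface_cols):
        d = records[["L_D", "a_D", "b_D"]].to_numpy() - records[
            ["L_B", "a_B", "b_B"]
        ].to_numpy()
        de = np.linalg.norm(d, axis=1)
        summary.loc["delta_e_DB"] = [de.min(), de.mean(), de.max()]
    summary.index.name = "column"
    return summary


def samples_from_frame(records: pd.DataFrame) -> list:
    """Convert generated (or read) records to training samples."""
    return [
        TrainingSample(
            pigments=PigmentLevel(srs=row.srs, lba=row.lba),
            target=CMQCoordinates(qL=row.qL, qa=row.qa, qb=row.qb),
        )
        for row in records.itertuples()
    ]
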