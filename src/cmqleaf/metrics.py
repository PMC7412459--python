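"""Agreement metrics, the model-comparison harness, and input sensitivity.

Model quality is scored per CMQ coordinate with R² and RMSE on a seeded
train/test split; agreement between predicted and observed series is further
summarized by Pearson's r and Lin's concordance coefficient ρ_c, which also
penalizes departure from the identity line.  Relative input influence on the
network's responses is estimated with a Monte-Carlo total-effect (Sobol-type)
sensitivity analysis over independent uniform pigment ranges.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import TanhNetwork, predict_cmq_batch
from .training import (
    FitConfig,
    PARAMETRIC_TERM_SETS,
    TrainingSample,
    fit_parametric,
    fit_tanh_network,
    predict_parametric_batch,
    samples_to_arrays,
)

__all__ = [
    "r_squared",
    "rmse",
    "pearson_r",
    "lins_concordance",
    "train_test_split",
    "model_comparison",
    "variable_importance",
]

_COORDS = ("qL", "qa", "qb")


def _paired(observed, predicted) -> tuple:
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("observed and predicted must be equal-length 1-d, n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series must be finite")
    return x, y


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (can be negative)."""
    x, y = _paired(observed, predicted)
    ss_tot = float(((x - x.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("observed series has zero variance")
    return 1.0 - float(((x - y) ** 2).sum()) / ss_tot


def rmse(observed, predicted) -> float:
    """Root mean squared prediction error."""
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("observed and predicted must be equal-length and nonempty")
    return float(np.sqrt(((x - y) ** 2).mean()))


def pearson_r(observed, predicted) -> float:
    """Product-moment correlation between the two series."""
    x, y = _paired(observed, predicted)
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("correlation undefined for a zero-variance series")
    return float(stats.pearsonr(x, y).statistic)


def lins_concordance(observed, predicted) -> float:
    """Lin's concordance ρ_c = 2 s_xy / (s_x² + s_y² + (x̄ - ȳ)²).

    Uses population (divide-by-n) moments, the original estimator;
    combines correlation with conformance to the identity line,
    so |ρ_c| <= |r| always.
    """
    x, y = _paired(observed, predicted)
    sx2, sy2 = x.var(), y.var()
    if sx2 == 0.0 or sy2 == 0.0:
        raise ValueError("concordance undefined for a zero-variance series")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2))


def train_test_split(
    samples: Sequence,
    fraction: float = 0.8,
    seed: int = 0,
    sizes: Optional[tuple] = None,
) -> tuple:
    """Seeded uniform split without replacement into (training, testing).

    By default the training part holds floor(n * fraction) items.  ``sizes``
    overrides the arithmetic with explicit (n_train, n_test) counts — e.g.
    (480, 124) to mirror the historical 604-leaf split exactly.
    """
    samples = list(samples)
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if sizes is not None:
        n_train, n_test = sizes
        if n_train + n_test != n:
            raise ValueError(f"sizes {sizes} do not add up to n = {n}")
    else:
        if not 0.0 < fraction < 1.0:
            raise ValueError("fraction must lie strictly between 0 and 1")
        n_train = int(np.floor(n * fraction))
        if n_train in (0, n):
            raise ValueError("split would leave an empty part")
    perm = np.random.default_rng(seed).permutation(n)
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    return [samples[i] for i in train_idx], [samples[i] for i in test_idx]


def model_comparison(
    training: Iterable[TrainingSample],
    testing: Iterable[TrainingSample],
    families: Iterable[str] = tuple(PARAMETRIC_TERM_SETS),
    network_config: FitConfig = FitConfig(),
) -> pd.DataFrame:
    """Fit every baseline family plus a tanh network; score both splits.

    Returns a table with one row per model and a (set, metric, coordinate)
    column hierarchy of R² and RMSE values per CMQ coordinate — the standard
    side-by-side comparison layout.
    """
    training, testing = list(training), list(testing)
    X_tr, Y_tr = samples_to_arrays(training)
    X_te, Y_te = samples_to_arrays(testing)

    predictors = {}
    for family in families:
        model = fit_parametric(training, family)
        predictors[family.replace("_", " ")] = (
            lambda X, m=model: predict_parametric_batch(m, X[:, 0], X[:, 1])
        )
    net = fit_tanh_network(training, network_config)
    predictors["tanh network"] = lambda X: predict_cmq_batch(net, X[:, 0], X[:, 1])

    columns = pd.MultiIndex.from_product(
        [("training", "testing"), ("R2", "RMSE"), _COORDS],
        names=("set", "metric", "coordinate"),
    )
    rows = {}
    for name, predict in predictors.items():
        vals = []
        for X, Y in ((X_tr, Y_tr), (X_te, Y_te)):
            P = predict(X)
            vals.extend(r_squared(Y[:, j], P[:, j]) for j in range(3))
            vals.extend(rmse(Y[:, j], P[:, j]) for j in range(3))
        rows[name] = vals
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index.name = "model"
    return table


def variable_importance(
    net: TanhNetwork,
    srs_range: tuple = (0.0, 8.6),
    lba_range: tuple = (0.1, 7.8),
    n: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo total-effect sensitivity of each response to each input.

    Draws two independent uniform sample matrices over the stated pigment
    ranges and applies the Jansen total-effect estimator
    S_Ti = E[(f(A) - f(A with column i from B))²] / (2 Var f); percentages
    are reported per response.  With independent inputs and an additive
    function this reduces to each input's share of the output variance.

    This is an approximate attribution; it characterizes which pigment
    drives each quasi-color coordinate, not an exact decomposition of any
    particular fitting procedure.
    """
    for name, (lo, hi) in (("srs", srs_range), ("lba", lba_range)):
        if not hi > lo:
            raise ValueError(f"degenerate {name} range {(lo, hi)}")
    rng = np.random.default_rng(seed)
    lows = np.array([srs_range[0], lba_range[0]])
    highs = np.array([srs_range[1], lba_range[1]])
    A = rng.uniform(lows, highs, size=(n, 2))
    B = rng.uniform(lows, highs, size=(n, 2))
    fA = predict_cmq_batch(net, A[:, 0], A[:, 1])
    var = fA.var(axis=0)
    out = np.empty((2, 3))
    for i in range(2):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi = predict_cmq_batch(net, ABi[:, 0], ABi[:, 1])
        num = ((fA - fABi) ** 2).mean(axis=0)
        # a constant response has no variance to attribute
        out[i] = np.divide(num, 2.0 * var, out=np.zeros(3), where=var > 0)
    return pd.DataFrame(
        100.0 * out, index=pd.Index(["srs", "lba"], name="input"), columns=_COORDS
    )
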