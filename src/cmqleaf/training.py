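"""Fitting quasi-color models to (pigment -> CMQ) data.

Two model classes are supported:

* the single-hidden-layer tanh network family (the class the published
  predictor belongs to), fitted by penalized least squares over all three
  responses jointly, with the hidden-layer width selected by repeated
  cross-validation on summed per-response Gaussian log-likelihoods; and
* three nested polynomial baselines in the two pigment inputs S = SR-S and
  A = Lb-A — full factorial {1, S, A, S·A}, quadratic polynomial
  {1, S, A, S², A²} and response surface {1, S, A, S·A, S², A²} — fitted by
  ordinary least squares per response.

Network fitting standardizes both inputs and responses internally for
conditioning and folds the standardization back into the returned weights,
so a fitted :class:`~cmqleaf.network.TanhNetwork` always operates on raw
SR-S/Lb-A and raw CMQ scales, like the published model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .colorimetry import CMQCoordinates
from .network import TanhNetwork, predict_cmq_batch
from .pigments import PigmentLevel

__all__ = [
    "TrainingSample",
    "FitConfig",
    "CVResult",
    "ParametricModel",
    "UnderdeterminedError",
    "PARAMETRIC_TERM_SETS",
    "fit_tanh_network",
    "negative_log_likelihood",
    "kfold_hidden_node_selection",
    "fit_parametric",
    "predict_parametric",
    "predict_parametric_batch",
    "samples_to_arrays",
]

#: tanh pre-activation scale used throughout the model family
_SCALE = 0.5
#: penalty grid searched when ``penalty="auto"``
_AUTO_PENALTY_GRID = (0.0, 1e-4, 1e-3, 1e-2, 1e-1)
#: variance floor in the Gaussian likelihood (guards the zero-residual limit)
VARIANCE_FLOOR = 1e-9


class UnderdeterminedError(ValueError):
    """Fewer samples than free parameters."""


@dataclass(frozen=True)
class TrainingSample:
    """One leaf: its averaged pigment levels and observed CMQ coordinates."""

    pigments: PigmentLevel
    target: CMQCoordinates

    def __post_init__(self) -> None:
        if not 0.0 <= self.target.qL <= 100.0:
            raise ValueError(f"observed qL = {self.target.qL} outside [0, 100]")


@dataclass(frozen=True)
class FitConfig:
    """Knobs for network fitting.

    penalty is the ridge coefficient on all weights (never biases), applied
    on the internal standardized scale; ``"auto"`` selects it from a small
    grid by validation likelihood on an internal 90/10 split and then refits
    on all data.  All randomness (restart initializations, auto-penalty
    split) derives from ``seed``.
    """

    hidden_count: int = 3
    penalty: Union[float, str] = 1e-4
    restarts: int = 10
    max_iterations: int = 2000
    tolerance: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_count < 1:
            raise ValueError("hidden_count must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if isinstance(self.penalty, str):
            if self.penalty != "auto":
                raise ValueError("penalty must be a non-negative number or 'auto'")
        elif self.penalty < 0:
            raise ValueError("penalty must be non-negative")


def samples_to_arrays(samples: Iterable[TrainingSample]) -> tuple:
    """(n, 2) pigment matrix and (n, 3) target matrix."""
    samples = list(samples)
    X = np.array([[s.pigments.srs, s.pigments.lba] for s in samples], dtype=float)
    Y = np.array([[s.target.qL, s.target.qa, s.target.qb] for s in samples], dtype=float)
    return X.reshape(-1, 2), Y.reshape(-1, 3)


# -- network fitting -------------------------------------------------------


def _unpack(theta: np.ndarray, h: int):
    i = 0
    hb = theta[i : i + h]
    i += h
    hw = theta[i : i + 2 * h].reshape(h, 2)
    i += 2 * h
    ob = theta[i : i + 3]
    i += 3
    ow = theta[i:].reshape(3, h)
    return hb, hw, ob, ow


def _loss_grad(theta: np.ndarray, X: np.ndarray, Y: np.ndarray, h: int, lam: float):
    hb, hw, ob, ow = _unpack(theta, h)
    pre = _SCALE * (hb + X @ hw.T)
    H = np.tanh(pre)
    R = (ob + H @ ow.T) - Y
    loss = 0.5 * float((R * R).sum()) + 0.5 * lam * (
        float((hw * hw).sum()) + float((ow * ow).sum())
    )
    g_ow = R.T @ H + lam * ow
    g_ob = R.sum(axis=0)
    G = (R @ ow) * (1.0 - H * H) * _SCALE
    g_hw = G.T @ X + lam * hw
    g_hb = G.sum(axis=0)
    grad = np.concatenate([g_hb, g_hw.ravel(), g_ob, g_ow.ravel()])
    return loss, grad


def _fit_standardized(
    Xs: np.ndarray,
    Ys: np.ndarray,
    h: int,
    lam: float,
    rng: np.random.Generator,
    config: FitConfig,
):
    """Best-of-restarts quasi-Newton fit on standardized data."""
    best = None
    any_converged = False
    n_par = 3 * h + 3 * (h + 1)
    for _ in range(config.restarts):
        theta0 = np.concatenate(
            [
                rng.normal(0.0, 1.0, h),  # hidden biases
                rng.normal(0.0, 1.5, 2 * h),  # hidden weights (X standardized)
                np.zeros(3),  # output biases (Y centered)
                rng.normal(0.0, 1.0 / np.sqrt(h), 3 * h),
            ]
        )
        res = minimize(
            _loss_grad,
            theta0,
            args=(Xs, Ys, h, lam),
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": config.max_iterations,
                "ftol": config.tolerance,
                "gtol": 1e-10,
            },
        )
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun:
            best = res
    # hitting the iteration cap on a flat plateau is fine; a large residual
    # gradient is not
    grad_norm = float(np.max(np.abs(best.jac)))
    if not any_converged and grad_norm > 1e-2 * (1.0 + abs(best.fun)):
        warnings.warn(
            f"no restart reached the convergence tolerance "
            f"(best loss {best.fun:.6g}, max |gradient| {grad_norm:.3g}, "
            f"{n_par} parameters, status: {best.message})",
            RuntimeWarning,
            stacklevel=3,
        )
    return best


def _destandardize(
    theta: np.ndarray, h: int, x_mean, x_sd, y_mean, y_sd
) -> TanhNetwork:
    hb, hw, ob, ow = _unpack(theta, h)
    hw_raw = hw / x_sd
    hb_raw = hb - hw_raw @ x_mean
    ow_raw = ow * y_sd[:, None]
    ob_raw = y_mean + ob * y_sd
    return TanhNetwork(
        hidden_weights=hw_raw,
        hidden_biases=hb_raw,
        output_weights=ow_raw,
        output_biases=ob_raw,
        pre_activation_scale=_SCALE,
    )


def fit_tanh_network(
    samples: Iterable[TrainingSample], config: FitConfig = FitConfig()
) -> TanhNetwork:
    """Fit a 2-H-3 tanh network by penalized least squares.

    The squared error is summed over the three responses with each response
    standardized to unit variance during fitting (so qL does not dominate by
    scale); the best of ``config.restarts`` random initializations is
    returned.  Deterministic for a given config and sample order-independent
    data content.

    Raises
    ------
    UnderdeterminedError
        If the sample count does not exceed the parameter count
        3H + 3(H + 1).
    """
    X, Y = samples_to_arrays(samples)
    h = config.hidden_count
    n_par = 3 * h + 3 * (h + 1)
    if X.shape[0] <= n_par:
        raise UnderdeterminedError(
            f"{X.shape[0]} samples cannot determine {n_par} parameters "
            f"(hidden_count={h})"
        )
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0)
    y_mean, y_sd = Y.mean(axis=0), Y.std(axis=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    y_sd = np.where(y_sd > 0, y_sd, 1.0)
    Xs = (X - x_mean) / x_sd
    Ys = (Y - y_mean) / y_sd

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, h]))
    if config.penalty == "auto":
        lam = _select_penalty(Xs, Ys, h, rng, config)
    else:
        lam = float(config.penalty)
    res = _fit_standardized(Xs, Ys, h, lam, rng, config)
    return _destandardize(res.x, h, x_mean, x_sd, y_mean, y_sd)


def _select_penalty(Xs, Ys, h, rng, config) -> float:
    """Pick the ridge penalty from the grid by held-out Gaussian NLL."""
    n = Xs.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, n // 10)
    val, tr = perm[:n_val], perm[n_val:]
    best_lam, best_nll = _AUTO_PENALTY_GRID[0], np.inf
    for lam in _AUTO_PENALTY_GRID:
        sub_rng = np.random.default_rng(np.random.SeedSequence([config.seed, h, 17]))
        res = _fit_standardized(
            Xs[tr], Ys[tr], h, lam, sub_rng, replace(config, restarts=max(1, config.restarts // 2))
        )
        hb, hw, ob, ow = _unpack(res.x, h)
        Hv = np.tanh(_SCALE * (hb + Xs[val] @ hw.T))
        R = (ob + Hv @ ow.T) - Ys[val]
        nll = _gaussian_nll_from_residuals(R)
        if nll < best_nll:
            best_lam, best_nll = lam, nll
    return best_lam


# -- likelihood ------------------------------------------------------------


def _gaussian_nll_from_residuals(R: np.ndarray, floor: float = VARIANCE_FLOOR) -> float:
    n = R.shape[0]
    sse = (R * R).sum(axis=0)
    var = np.maximum(sse / n, floor)
    return float((0.5 * n * np.log(2.0 * np.pi * var) + sse / (2.0 * var)).sum())


def negative_log_likelihood(
    net: TanhNetwork,
    samples: Iterable[TrainingSample],
    variance_floor: float = VARIANCE_FLOOR,
) -> float:
    """Summed Gaussian negative log-likelihood over the three responses.

    Each response uses the plug-in variance estimate (its mean squared
    residual, floored at ``variance_floor``); the per-response NLLs are
    added, matching the multi-response model-selection statistic.
    """
    X, Y = samples_to_arrays(samples)
    if X.shape[0] == 0:
        raise ValueError("negative_log_likelihood requires at least one sample")
    R = predict_cmq_batch(net, X[:, 0], X[:, 1]) - Y
    return _gaussian_nll_from_residuals(R, variance_floor)


# -- hidden-node selection -------------------------------------------------


@dataclass(frozen=True)
class CVResult:
    """Outcome of the repeated cross-validation sweep over hidden widths."""

    node_counts: tuple
    validation_nll: np.ndarray  # (repeats, len(node_counts))
    selected_count: int

    @property
    def mean_validation_nll(self) -> np.ndarray:
        return self.validation_nll.mean(axis=0)

    @property
    def se_validation_nll(self) -> np.ndarray:
        r = self.validation_nll.shape[0]
        return self.validation_nll.std(axis=0, ddof=1) / np.sqrt(r) if r > 1 else np.zeros(
            len(self.node_counts)
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (node_count, repeat, validation_nll) for CSV export."""
        reps, nodes = self.validation_nll.shape
        return pd.DataFrame(
            {
                "node_count": np.tile(self.node_counts, reps),
                "repeat": np.repeat(np.arange(reps), nodes),
                "validation_nll": self.validation_nll.ravel(),
            }
        )


def _one_se_selection(node_counts, mean_nll, se_nll) -> int:
    """Smallest width whose mean NLL is within one SE of the minimum."""
    i_min = int(np.argmin(mean_nll))
    threshold = mean_nll[i_min] + se_nll[i_min]
    for count, m in zip(node_counts, mean_nll):
        if m <= threshold:
            return int(count)
    return int(node_counts[i_min])


def kfold_hidden_node_selection(
    samples: Sequence[TrainingSample],
    k: int = 10,
    repeats: int = 20,
    node_range: Iterable[int] = range(1, 26),
    config: FitConfig = FitConfig(),
    method: str = "single-split",
) -> CVResult:
    """Select the hidden-layer width by repeated validation likelihood.

    With ``method="single-split"`` each repeat draws one random (k-1):1
    train/validation split (for k = 10, a 9:1 split) and scores every
    candidate width on it; ``method="rotation"`` instead runs a full k-fold
    rotation per repeat and sums the fold NLLs.  Validation NLL is averaged
    over repeats per width, and the selected width is the smallest one whose
    mean is within one standard error of the minimum (parsimony tie-break).
    """
    samples = list(samples)
    n = len(samples)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if method not in ("single-split", "rotation"):
        raise ValueError("method must be 'single-split' or 'rotation'")
    node_counts = tuple(int(c) for c in node_range)
    master = np.random.SeedSequence(config.seed)
    split_seeds = master.spawn(repeats)
    nll = np.empty((repeats, len(node_counts)))
    for r, split_seed in enumerate(split_seeds):
        rng = np.random.default_rng(split_seed)
        perm = rng.permutation(n)
        if method == "single-split":
            folds = [perm[: n // k]]
        else:
            folds = np.array_split(perm, k)
        for j, h in enumerate(node_counts):
            total = 0.0
            for fold in folds:
                mask = np.ones(n, dtype=bool)
                mask[fold] = False
                train = [samples[i] for i in np.nonzero(mask)[0]]
                val = [samples[i] for i in fold]
                fit_cfg = replace(
                    config,
                    hidden_count=h,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                net = fit_tanh_network(train, fit_cfg)
                total += negative_log_likelihood(net, val)
            nll[r, j] = total
    mean = nll.mean(axis=0)
    se = (
        nll.std(axis=0, ddof=1) / np.sqrt(repeats)
        if repeats > 1
        else np.zeros(len(node_counts))
    )
    return CVResult(
        node_counts=node_counts,
        validation_nll=nll,
        selected_count=_one_se_selection(node_counts, mean, se),
    )


# -- polynomial baselines --------------------------------------------------

PARAMETRIC_TERM_SETS = {
    "full_factorial": ("1", "S", "A", "S*A"),
    "quadratic_polynomial": ("1", "S", "A", "S^2", "A^2"),
    "response_surface": ("1", "S", "A", "S*A", "S^2", "A^2"),
}

_TERM_FUNCS = {
    "1": lambda S, A: np.ones_like(S),
    "S": lambda S, A: S,
    "A": lambda S, A: A,
    "S*A": lambda S, A: S * A,
    "S^2": lambda S, A: S * S,
    "A^2": lambda S, A: A * A,
}


@dataclass(frozen=True)
class ParametricModel:
    """Per-response OLS coefficients over one polynomial term set."""

    family: str
    coefficients: np.ndarray  # (3, n_terms), response rows (qL, qa, qb)

    @property
    def terms(self) -> tuple:
        return PARAMETRIC_TERM_SETS[self.family]


def _design_matrix(X: np.ndarray, family: str) -> np.ndarray:
    S, A = X[:, 0], X[:, 1]
    return np.column_stack([_TERM_FUNCS[t](S, A) for t in PARAMETRIC_TERM_SETS[family]])


def fit_parametric(samples: Iterable[TrainingSample], family: str) -> ParametricModel:
    """Exact per-response OLS fit of one polynomial family."""
    if family not in PARAMETRIC_TERM_SETS:
        raise ValueError(
            f"unknown family {family!r}; choose from {sorted(PARAMETRIC_TERM_SETS)}"
        )
    X, Y = samples_to_arrays(samples)
    D = _design_matrix(X, family)
    if X.shape[0] <= D.shape[1]:
        raise UnderdeterminedError(
            f"{X.shape[0]} samples cannot determine {D.shape[1]} terms of {family}"
        )
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design for {family}: pigment values do not span the term set"
        )
    coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    return ParametricModel(family=family, coefficients=coef.T)


def predict_parametric_batch(model: ParametricModel, srs, lba) -> np.ndarray:
    X = np.column_stack([np.asarray(srs, dtype=float), np.asarray(lba, dtype=float)])
    return _design_matrix(X, model.family) @ model.coefficients.T


def predict_parametric(model: ParametricModel, p: PigmentLevel) -> CMQCoordinates:
    y = predict_parametric_batch(model, [p.srs], [p.lba])[0]
    return CMQCoordinates(qL=float(y[0]), qa=float(y[1]), qb=float(y[2]))
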