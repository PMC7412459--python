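"""Network fitting, likelihood, node selection, and polynomial baselines."""

import math

import numpy as np
import pytest

from cmqleaf import (
    CMQCoordinates,
    FitConfig,
    PigmentLevel,
    TrainingSample,
    UnderdeterminedError,
    fit_parametric,
    fit_tanh_network,
    kfold_hidden_node_selection,
    negative_log_likelihood,
    predict_cmq_batch,
    predict_parametric,
)
from cmqleaf.training import (
    PARAMETRIC_TERM_SETS,
    VARIANCE_FLOOR,
    predict_parametric_batch,
    samples_to_arrays,
)


def _samples(X, Y):
    return [
        TrainingSample(PigmentLevel(*x), CMQCoordinates(*y)) for x, y in zip(X, Y)
    ]


def _grid_samples(net, n_side=20):
    s = np.linspace(0, 9.7, n_side)
    a = np.linspace(0, 8.0, n_side)
    S, A = np.meshgrid(s, a, indexing="ij")
    X = np.column_stack([S.ravel(), A.ravel()])
    Y = predict_cmq_batch(net, X[:, 0], X[:, 1])
    return X, Y


# -- tanh network fitting --------------------------------------------------


def test_function_recovery_from_noiseless_grid(net):
    """A 3-node fit to noiseless published-net data recovers the surface.

    Weights are only identified up to hidden-unit permutation/sign, so the
    check is on predictions, not coefficients.
    """
    X, Y = _grid_samples(net)
    fitted = fit_tanh_network(
        _samples(X, Y),
        FitConfig(hidden_count=3, penalty=0.0, restarts=10, max_iterations=5000, seed=7),
    )
    P = predict_cmq_batch(fitted, X[:, 0], X[:, 1])
    assert np.max(np.abs(P - Y)) < 0.5


def test_underdetermined_fit_rejected(net):
    X, Y = _grid_samples(net, n_side=3)
    with pytest.raises(UnderdeterminedError):
        fit_tanh_network(_samples(X[:5], Y[:5]), FitConfig(hidden_count=3))


def test_fit_deterministic_given_seed(net):
    X, Y = _grid_samples(net, n_side=6)
    rng = np.random.default_rng(0)
    Yn = Y + rng.normal(0, 1.0, Y.shape)
    cfg = FitConfig(hidden_count=2, restarts=3, seed=11, max_iterations=300)
    n1 = fit_tanh_network(_samples(X, Yn), cfg)
    n2 = fit_tanh_network(_samples(X, Yn), cfg)
    assert np.array_equal(n1.hidden_weights, n2.hidden_weights)
    assert np.array_equal(n1.output_weights, n2.output_weights)


# -- likelihood ------------------------------------------------------------


def test_nll_zero_residual_limit(net):
    """Perfect predictions land on the variance floor: 3n/2 * ln(2πε)."""
    X, Y = _grid_samples(net, n_side=4)
    samples = _samples(X, Y)
    n = len(samples)
    expected = 3 * n * 0.5 * math.log(2 * math.pi * VARIANCE_FLOOR)
    assert negative_log_likelihood(net, samples) == pytest.approx(expected, rel=1e-9)


def test_nll_increases_when_residuals_double(net):
    X, Y = _grid_samples(net, n_side=4)
    rng = np.random.default_rng(1)
    E = rng.normal(0, 1.0, Y.shape)
    nll1 = negative_log_likelihood(net, _samples(X, Y + E))
    nll2 = negative_log_likelihood(net, _samples(X, Y + 2 * E))
    assert nll2 > nll1


def test_nll_matches_closed_form_hand_computation(net):
    """Two samples, residuals only in qL: NLL = Gaussian NLL + two floored terms."""
    X = np.array([[2.0, 1.0], [6.0, 3.0]])
    Y = predict_cmq_batch(net, X[:, 0], X[:, 1])
    Yobs = Y.copy()
    Yobs[:, 0] += [1.0, -2.0]  # qL residuals -1, 2
    var_qL = (1.0 + 4.0) / 2.0
    closed = (
        2 * 0.5 * math.log(2 * math.pi * var_qL)
        + 5.0 / (2 * var_qL)
        + 2 * (2 * 0.5 * math.log(2 * math.pi * VARIANCE_FLOOR))
    )
    assert negative_log_likelihood(net, _samples(X, Yobs)) == pytest.approx(closed, rel=1e-9)


def test_nll_rejects_empty(net):
    with pytest.raises(ValueError):
        negative_log_likelihood(net, [])


# -- node selection --------------------------------------------------------


def _rank_one_linear_samples(n=80, seed=0, noise_sd=0.3):
    """All three responses track the same linear pigment contrast, so a
    single hidden unit suffices to represent the surface."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([rng.uniform(0, 9, n), rng.uniform(0, 8, n)])
    z = 2.0 * X[:, 0] - 1.0 * X[:, 1]
    Y = np.column_stack([40.0 + 1.5 * z, 1.0 - z, 10.0 + 0.5 * z])
    Y += rng.normal(0, noise_sd, Y.shape)
    Y[:, 0] = np.clip(Y[:, 0], 0, 100)
    return _samples(X, Y)


def test_one_se_rule_prefers_parsimony_on_single_unit_data():
    """When one hidden unit already explains the data, wider nets don't win."""
    result = kfold_hidden_node_selection(
        _rank_one_linear_samples(),
        k=10,
        repeats=3,
        node_range=(1, 2, 3),
        config=FitConfig(restarts=3, seed=5, max_iterations=2000, penalty=0.0),
    )
    assert result.selected_count == 1


def test_cv_reproducible_and_order_invariant(net):
    X, Y = _grid_samples(net, n_side=7)
    rng = np.random.default_rng(2)
    Yn = Y + rng.normal(0, 1.5, Y.shape)
    samples = _samples(X, Yn)
    cfg = FitConfig(restarts=2, seed=9, max_iterations=300)
    kwargs = dict(k=10, repeats=1, node_range=(1, 2), config=cfg)
    r1 = kfold_hidden_node_selection(samples, **kwargs)
    r2 = kfold_hidden_node_selection(samples, **kwargs)
    assert np.array_equal(r1.validation_nll, r2.validation_nll)
    assert r1.selected_count == r2.selected_count


def test_cv_rejects_k_larger_than_sample_count(net):
    X, Y = _grid_samples(net, n_side=2)
    with pytest.raises(ValueError):
        kfold_hidden_node_selection(_samples(X[:3], Y[:3]), k=10)


def test_cv_result_export_layout(net):
    X, Y = _grid_samples(net, n_side=7)
    samples = _samples(X, Y + 1.0)
    res = kfold_hidden_node_selection(
        samples, repeats=2, node_range=(1,), config=FitConfig(restarts=1, max_iterations=100)
    )
    frame = res.to_frame()
    assert list(frame.columns) == ["node_count", "repeat", "validation_nll"]
    assert len(frame) == 2


# -- polynomial baselines --------------------------------------------------


def test_full_factorial_recovers_generating_coefficients():
    rng = np.random.default_rng(3)
    X = np.column_stack([rng.uniform(0, 9, 50), rng.uniform(0, 8, 50)])
    y = 1.0 + 2.0 * X[:, 0] + 3.0 * X[:, 1] + 4.0 * X[:, 0] * X[:, 1]
    Y = np.column_stack([np.full(50, 40.0), y, y])
    model = fit_parametric(_samples(X, Y), "full_factorial")
    assert model.coefficients[1] == pytest.approx([1.0, 2.0, 3.0, 4.0], abs=1e-8)
    # constant response: intercept only
    assert model.coefficients[0] == pytest.approx([40.0, 0.0, 0.0, 0.0], abs=1e-8)


def test_response_surface_exact_on_full_quadratic():
    rng = np.random.default_rng(4)
    X = np.column_stack([rng.uniform(0, 9, 60), rng.uniform(0, 8, 60)])
    coefs = np.array([5.0, 1.0, -2.0, 0.5, 0.25, -0.75])
    S, A = X[:, 0], X[:, 1]
    y = coefs @ np.stack([np.ones(60), S, A, S * A, S * S, A * A])
    Y = np.column_stack([np.full(60, 50.0), y, -y])
    model = fit_parametric(_samples(X, Y), "response_surface")
    assert model.coefficients[1] == pytest.approx(coefs, abs=1e-8)


def test_term_sets_nested():
    rs = set(PARAMETRIC_TERM_SETS["response_surface"])
    assert set(PARAMETRIC_TERM_SETS["full_factorial"]) < rs
    assert set(PARAMETRIC_TERM_SETS["quadratic_polynomial"]) < rs


def test_nested_families_order_training_sse(net):
    """Response surface can never fit worse than its nested sub-families."""
    X, Y = _grid_samples(net, n_side=10)
    rng = np.random.default_rng(5)
    samples = _samples(X, Y + rng.normal(0, 1.5, Y.shape))
    _, Yarr = samples_to_arrays(samples)
    sse = {}
    for family in PARAMETRIC_TERM_SETS:
        model = fit_parametric(samples, family)
        P = predict_parametric_batch(model, X[:, 0], X[:, 1])
        sse[family] = ((P - Yarr) ** 2).sum()
    assert sse["response_surface"] <= sse["full_factorial"] + 1e-9
    assert sse["response_surface"] <= sse["quadratic_polynomial"] + 1e-9


def test_predict_parametric_matches_manual_evaluation():
    rng = np.random.default_rng(6)
    X = np.column_stack([rng.uniform(0, 9, 30), rng.uniform(0, 8, 30)])
    Y = rng.normal(40, 5, (30, 3))
    Y[:, 0] = np.clip(Y[:, 0], 0, 100)
    model = fit_parametric(_samples(X, Y), "response_surface")
    s, a = 3.3, 2.1
    terms = np.array([1.0, s, a, s * a, s * s, a * a])
    manual = model.coefficients @ terms
    pred = predict_parametric(model, PigmentLevel(s, a))
    assert (pred.qL, pred.qa, pred.qb) == pytest.approx(tuple(manual))


def test_unknown_family_rejected():
    with pytest.raises(ValueError):
        fit_parametric([], "cubic_spline")
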