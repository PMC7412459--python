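"""Agreement metrics, splitting, model comparison, input sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmqleaf import (
    FitConfig,
    TanhNetwork,
    lins_concordance,
    model_comparison,
    pearson_r,
    r_squared,
    rmse,
    train_test_split,
    variable_importance,
)
from cmqleaf.network import predict_cmq_batch
from cmqleaf.simulate import GeneratorConfig, generate_leaf_samples, samples_from_frame

series = st.lists(st.floats(-50, 50, allow_nan=False), min_size=3, max_size=30)


def test_r_squared_examples():
    assert r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert r_squared([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0)
    assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)


def test_rmse_examples():
    assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
    assert rmse([1, 2, 3], [3, 4, 5]) == pytest.approx(2.0)  # constant offset
    assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))


def test_pearson_examples():
    x = np.arange(10.0)
    assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)
    assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.98198, abs=1e-4)


def test_lins_concordance_examples():
    x = np.arange(5.0)
    assert lins_concordance(x, x) == pytest.approx(1.0)
    assert lins_concordance([1, 2, 3], [2, 3, 4]) == pytest.approx(4.0 / 7.0)


def test_zero_variance_rejected():
    for f in (r_squared, pearson_r, lins_concordance):
        with pytest.raises(ValueError):
            f([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


@given(series, series)
@settings(max_examples=200)
def test_concordance_never_exceeds_correlation(x, y):
    x, y = np.asarray(x), np.asarray(y)
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    # near-constant series are numerically degenerate for both estimators
    if np.ptp(x) < 1e-6 or np.ptp(y) < 1e-6:
        return
    assert abs(lins_concordance(x, y)) <= abs(pearson_r(x, y)) + 1e-9


def test_concordance_equals_correlation_when_moments_match():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = 2 * x.mean() - x  # same mean and variance, reversed
    assert lins_concordance(x, y) == pytest.approx(pearson_r(x, y))


@given(series, series)
@settings(max_examples=100)
def test_r_squared_rmse_consistency_identity(x, y):
    x, y = np.asarray(x), np.asarray(y)
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    if np.ptp(x) < 1e-6:
        return
    ss_tot = ((x - x.mean()) ** 2).sum()
    assert r_squared(x, y) == pytest.approx(
        1 - rmse(x, y) ** 2 * n / ss_tot, rel=1e-9, abs=1e-9
    )


# -- splitting -------------------------------------------------------------


def test_split_sizes_and_determinism():
    items = list(range(604))
    tr, te = train_test_split(items, fraction=0.8, seed=1)
    assert (len(tr), len(te)) == (483, 121)
    tr2, te2 = train_test_split(items, fraction=0.8, seed=1)
    assert tr == tr2 and te == te2
    assert sorted(tr + te) == items  # disjoint union


def test_split_explicit_size_override():
    tr, te = train_test_split(list(range(604)), seed=1, sizes=(480, 124))
    assert (len(tr), len(te)) == (480, 124)
    with pytest.raises(ValueError):
        train_test_split(list(range(10)), sizes=(5, 4))


def test_split_rejects_degenerate():
    with pytest.raises(ValueError):
        train_test_split([1], fraction=0.5)
    with pytest.raises(ValueError):
        train_test_split(list(range(10)), fraction=1.5)


# -- comparison harness ----------------------------------------------------


def test_model_comparison_on_noiseless_network_data(net):
    """The network family fits its own noiseless surface; polynomials cannot."""
    df = generate_leaf_samples(
        GeneratorConfig(n=260, noise_sd=(0, 0, 0), asymmetry_mean_delta_e=0, seed=8)
    )
    samples = samples_from_frame(df)
    tr, te = train_test_split(samples, seed=8)
    table = model_comparison(
        tr, te, network_config=FitConfig(restarts=6, seed=8, max_iterations=3000)
    )
    net_rmse = table.loc["tanh network", ("training", "RMSE")]
    for family in ("full factorial", "quadratic polynomial", "response surface"):
        assert (net_rmse < table.loc[family, ("training", "RMSE")]).all()
    assert (net_rmse < 0.5).all()
    # nested OLS: response surface never trains worse than full factorial
    ff = table.loc["full factorial", ("training", "RMSE")]
    rs = table.loc["response surface", ("training", "RMSE")]
    assert (rs <= ff + 1e-9).all()


# -- input sensitivity -----------------------------------------------------


def _single_input_net():
    # qL responds to srs only; qa to lba only; qb constant-ish
    return TanhNetwork(
        hidden_weights=np.array([[1.0, 0.0], [0.0, 1.0]]),
        hidden_biases=np.array([0.0, 0.0]),
        output_weights=np.array([[10.0, 0.0], [0.0, 10.0], [0.0, 0.0]]),
        output_biases=np.array([50.0, 0.0, 20.0]),
        pre_activation_scale=0.2,
    )


def test_importance_isolates_single_input_dependence():
    imp = variable_importance(_single_input_net(), n=4000, seed=3)
    assert imp.loc["srs", "qL"] > 95.0 and imp.loc["lba", "qL"] < 5.0
    assert imp.loc["lba", "qa"] > 95.0 and imp.loc["srs", "qa"] < 5.0


def test_importance_additive_linear_matches_variance_shares():
    """Near-linear additive response splits variance as slope² × input variance."""
    net = TanhNetwork(
        hidden_weights=np.array([[0.01, 0.0], [0.0, 0.01]]),
        hidden_biases=np.array([0.0, 0.0]),
        output_weights=np.array([[200.0, 100.0]] * 3),
        output_biases=np.zeros(3),
        pre_activation_scale=1.0,
    )
    # effective slopes 2 and 1; var U(0,8.6) scales with width²
    v_s = 2.0**2 * 8.6**2 / 12
    v_a = 1.0**2 * 7.7**2 / 12
    imp = variable_importance(net, (0, 8.6), (0.1, 7.8), n=60000, seed=4)
    assert imp.loc["srs", "qL"] == pytest.approx(100 * v_s / (v_s + v_a), abs=2.0)
    assert imp.loc["lba", "qL"] == pytest.approx(100 * v_a / (v_s + v_a), abs=2.0)


def test_anthocyanin_dominates_quasi_lightness(net):
    imp = variable_importance(net, (0.0, 8.6), (0.1, 7.8), n=20000, seed=5)
    assert imp.loc["lba", "qL"] > imp.loc["srs", "qL"]
    assert imp.loc["lba", "qb"] > imp.loc["srs", "qb"]


def test_importance_rejects_degenerate_range(net):
    with pytest.raises(ValueError):
        variable_importance(net, (3.0, 3.0), (0.0, 8.0))
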