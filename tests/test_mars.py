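"""Spline engine: GCV closed forms, forward/backward passes against brute
force and simulation oracles, cross-validation, grid search and
preferred-model selection."""

import math

import numpy as np
import pandas as pd
import pytest

from bophmars.basis import HingeFactor, HingeTerm, SplineModel
from bophmars.mars import (
    FitConfig,
    GridResult,
    backward_pass,
    candidate_knots,
    cv_r2,
    fit,
    forward_pass,
    gcv,
    gcv_r2,
    gcv_r2_from_stats,
    grid_search,
    select_preferred,
)


# -- GCV closed forms -------------------------------------------------------


@pytest.mark.parametrize(
    "rss, n, complexity, expected",
    [
        (0.0, 50, 7, 0.0),
        (10.0, 10, 2, 1.5625),  # (10/10) / (1 - 2/10)^2 by hand
        (10.0, 10, 0, 1.0),
    ],
)
def test_gcv_closed_form(rss, n, complexity, expected):
    assert gcv(rss, n, complexity) == pytest.approx(expected)


def test_gcv_infinite_penalty_and_validation():
    assert math.isinf(gcv(1.0, 10, 10))
    assert math.isinf(gcv(1.0, 10, 12))
    with pytest.raises(ValueError):
        gcv(1.0, 10, -1)


def test_gcv_r2_plug_in_values():
    assert gcv_r2_from_stats(0.0, 2.0) == 1.0
    assert gcv_r2_from_stats(1.5625, 2.0) == pytest.approx(0.21875)
    with pytest.raises(ValueError):
        gcv_r2_from_stats(1.0, 0.0)


def test_intercept_only_gcv_r2_slightly_negative(rng):
    """With complexity 1, the GCV penalty exceeds the fit of an
    intercept-only model, so GCV R2 dips below zero at small n."""
    n = 10
    y = rng.normal(size=n)
    tab = pd.DataFrame({"y": y, "a": rng.normal(size=n), "b": rng.normal(size=n)})
    model = backward_pass([], tab, "y", FitConfig())
    assert model.gcv_r2 < 0
    # closed form: 1 - (1 - 1/n)^-2
    assert model.gcv_r2 == pytest.approx(1 - (1 - 1 / n) ** -2, rel=1e-9)


# -- forward pass -----------------------------------------------------------


def _grid_table(rng, n=200):
    x = np.tile([0.0, 0.5, 1.0, 1.5, 2.0], n // 5)
    return pd.DataFrame(
        {"x": x, "z": rng.normal(size=n), "y": np.maximum(0.0, x - 1.0)}
    )


def test_forward_recovers_noiseless_hinge_knot(rng):
    tab = _grid_table(rng)
    fwd = forward_pass(tab, "y", FitConfig(model_type=1, max_basis=10, min_span=1))
    first = fwd.terms[0].factors[0]
    assert first.variable == "x" and first.knot == 1.0
    assert fwd.rss_path[-1] == pytest.approx(0.0, abs=1e-18)


def test_forward_type0_is_ols(rng):
    x = rng.normal(size=300)
    y = 2.0 * x + rng.normal(0, 0.1, 300)
    tab = pd.DataFrame({"x": x, "z": rng.normal(size=300), "y": y})
    model = fit(tab, "y", FitConfig(model_type=0, max_basis=10))
    assert all(f.knot is None for t, _ in model.terms for f in t.factors)
    sel = [t.factors[0].variable for t, _ in model.terms]
    assert "x" in sel
    # OLS oracle on the selected design
    B = np.column_stack([np.ones(300)] + [tab[v] for v in sel])
    beta = np.linalg.lstsq(B, y, rcond=None)[0]
    slope = dict((v, c) for (t, c), v in zip(model.terms, sel))["x"]
    assert slope == pytest.approx(beta[1 + sel.index("x")], abs=1e-8)
    assert slope == pytest.approx(2.0, abs=0.05)


def test_constant_response_gives_intercept_only():
    tab = pd.DataFrame({"x": [1.0, 2, 3, 4], "z": [0.0, 1, 0, 1], "y": 5.0})
    fwd = forward_pass(tab, "y", FitConfig())
    assert fwd.terms == []
    model = fit(tab, "y", FitConfig())
    assert model.terms == [] and model.intercept == pytest.approx(5.0)


def _brute_force_first_pair(tab, response):
    """Independent oracle: enumerate every (variable, interior observed
    knot) reflected pair and minimize RSS of OLS on [1, h+, h-]."""
    y = tab[response].to_numpy(float)
    best = (np.inf, None, None)
    for var in tab.columns:
        if var == response:
            continue
        x = tab[var].to_numpy(float)
        xs = np.sort(x)
        for c in np.unique(xs[1:-1]):
            B = np.column_stack(
                [np.ones_like(x), np.maximum(0, x - c), np.maximum(0, c - x)]
            )
            resid = y - B @ np.linalg.lstsq(B, y, rcond=None)[0]
            rss = float(resid @ resid)
            if rss < best[0] - 1e-12:
                best = (rss, var, c)
    return best[1], best[2]


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_first_term_matches_brute_force(seed):
    """Exhaustive-oracle equivalence on tables of <= 30 rows x 3 variables."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(15, 31))
    tab = pd.DataFrame({f"v{j}": rng.normal(size=n) for j in range(3)})
    tab["y"] = (
        np.maximum(0, tab["v0"] - 0.2)
        + 0.5 * tab["v1"]
        + rng.normal(0, 0.3, n)
    )
    fwd = forward_pass(tab, "y", FitConfig(model_type=1, min_span=1, max_basis=4))
    got = fwd.terms[0].factors[0]
    var, knot = _brute_force_first_pair(tab, "y")
    assert (got.variable, got.knot) == (var, pytest.approx(knot))


def test_noiseless_hinge_heldout_r2_is_one(rng):
    train = _grid_table(rng, n=150)
    model = fit(train, "y", FitConfig(model_type=1, min_span=1, max_basis=10))
    x_new = rng.uniform(0, 2, 500)
    y_new = np.maximum(0, x_new - 1.0)
    pred = model.predict(pd.DataFrame({"x": x_new, "z": rng.normal(size=500)}))
    sse = np.sum((y_new - pred) ** 2)
    assert 1 - sse / np.sum((y_new - y_new.mean()) ** 2) == pytest.approx(1.0, abs=1e-9)


def test_forward_rss_never_increases(rng):
    n = 150
    tab = pd.DataFrame({f"v{j}": rng.normal(size=n) for j in range(4)})
    tab["y"] = np.sin(tab["v0"]) + 0.3 * tab["v1"] + rng.normal(0, 0.2, n)
    fwd = forward_pass(tab, "y", FitConfig(model_type=1, max_basis=20))
    assert (np.diff(fwd.rss_path) <= 1e-9).all()


def test_min_span_limits_candidate_knots():
    x = np.arange(30.0)
    k1 = candidate_knots(x, min_span=1)
    k5 = candidate_knots(x, min_span=5)
    assert set(k5) <= set(x)
    assert len(k5) < len(k1)
    # every knot keeps min_span observations on each side
    assert k5.min() >= x[4] and k5.max() <= x[-6]


# -- backward pass ----------------------------------------------------------


def test_backward_prunes_pure_noise_term():
    hits = 0
    reps = 20
    for s in range(reps):
        rng = np.random.default_rng(100 + s)
        n = 300
        x = rng.uniform(-1, 1, n)
        z = rng.normal(size=n)
        y = 3.0 * np.maximum(0, x - 0.2) + rng.normal(0, 0.3, n)
        tab = pd.DataFrame({"x": x, "z": z, "y": y})
        model = fit(tab, "y", FitConfig(model_type=1, max_basis=8))
        if "z" not in model.variables:
            hits += 1
    assert hits >= int(0.8 * reps)


def test_backward_all_noise_selects_intercept_only(rng):
    n = 100
    y = rng.normal(size=n)
    tab = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n), "y": y})
    noise_terms = [
        HingeTerm((HingeFactor("a", 0.1, "+"),)),
        HingeTerm((HingeFactor("a", 0.1, "-"),)),
        HingeTerm((HingeFactor("b", -0.3, "+"),)),
        HingeTerm((HingeFactor("b", -0.3, "-"),)),
    ]
    model = backward_pass(noise_terms, tab, "y", FitConfig(model_type=1))
    assert model.terms == []


def test_gcv_r2_bounded_by_ordinary_r2(rng):
    n = 200
    tab = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
    tab["y"] = tab["x"] ** 2 + rng.normal(0, 0.5, n)
    model = fit(tab, "y", FitConfig(model_type=1, max_basis=10))
    sst = float(np.sum((tab["y"] - tab["y"].mean()) ** 2))
    ordinary = 1 - model.rss / sst
    assert model.complexity > 0
    assert model.gcv_r2 <= ordinary


def test_model_predictions_match_termwise_evaluation(rng):
    """Fitted model predictions equal intercept + sum of coef * basis,
    evaluated term by term by an independent loop."""
    n = 200
    tab = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
    tab["y"] = np.abs(tab["x"]) + 0.5 * tab["z"] + rng.normal(0, 0.2, n)
    model = fit(tab, "y", FitConfig(model_type=1, max_basis=12))
    manual = np.full(n, model.intercept)
    for term, coef in model.terms:
        col = np.ones(n)
        for f in term.factors:
            v = tab[f.variable].to_numpy()
            if f.knot is None:
                col = col * v
            elif f.direction == "+":
                col = col * np.maximum(0, v - f.knot)
            else:
                col = col * np.maximum(0, f.knot - v)
        manual += coef * col
    np.testing.assert_allclose(model.predict(tab), manual, atol=1e-10)


# -- cross-validation -------------------------------------------------------


def test_cv_r2_matches_population_r2(rng):
    n = 800
    x = rng.normal(size=n)
    noise = rng.normal(size=n)
    y = x + noise  # population R2 = 0.5
    tab = pd.DataFrame({"x": x, "z": rng.normal(size=n), "y": y})
    cfg = FitConfig(model_type=1, max_basis=10, seed=3)
    val = cv_r2(tab, "y", cfg)
    assert val == pytest.approx(0.5, abs=0.05)
    assert cv_r2(tab, "y", cfg) == val  # identical seed, identical value


def test_cv_r2_null_response_near_zero(rng):
    n = 1000
    tab = pd.DataFrame(
        {"a": rng.normal(size=n), "b": rng.normal(size=n), "y": rng.normal(size=n)}
    )
    assert cv_r2(tab, "y", FitConfig(model_type=1, max_basis=10, seed=0)) <= 0.02


def test_cv_r2_requires_enough_rows():
    tab = pd.DataFrame({"x": [1.0, 2.0], "z": [0.0, 1.0], "y": [0.0, 1.0]})
    with pytest.raises(ValueError):
        cv_r2(tab, "y", FitConfig(folds=10))


# -- grid search and model selection ---------------------------------------


def test_grid_search_record_counts(rng):
    n = 120
    tab = pd.DataFrame({f"v{j}": rng.normal(size=n) for j in range(4)})
    tab["y"] = tab["v0"] + rng.normal(0, 1.0, n)
    sets = {"large": ["v0", "v1", "v2", "v3"], "medium": ["v0", "v1"], "small": ["v0", "v1"]}
    results = grid_search(tab, "y", sets)
    assert len(results) == 72  # 3 sets x 3 types x 4 sizes x 2 penalties
    one = grid_search(
        tab, "y", {"small": ["v0", "v1"]},
        model_types=[1], max_basis_values=[10], entry_penalties=[0.0],
    )
    assert len(one) == 1
    r2s = [r.gcv_r2 for r in results]
    assert sorted(r2s, reverse=True)[0] == max(r2s)


def _dummy_result(gcv_r2, n_vars, n_params, order, model_type=1):
    cfg = FitConfig(model_type=model_type)
    model = SplineModel(0.0, [], gcv_r2=gcv_r2)
    return GridResult("s", cfg, model, gcv_r2, n_params, n_vars, order)


def test_select_preferred_parsimony_rule():
    results = [
        _dummy_result(0.40, 12, 20, 0),
        _dummy_result(0.395, 6, 10, 1),
        _dummy_result(0.37, 3, 5, 2),
    ]
    assert select_preferred(results, tolerance=0.01).n_vars == 6


def test_select_preferred_single_and_ties():
    only = [_dummy_result(0.3, 4, 6, 0)]
    assert select_preferred(only) is only[0]
    tie = [_dummy_result(0.3, 4, 6, 0), _dummy_result(0.3, 4, 6, 1)]
    assert select_preferred(tie) is tie[0]  # stable order breaks exact ties
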