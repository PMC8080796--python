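"""LASSO path + stability selection, stepwise AIC, diagnostic models."""

import numpy as np
import pandas as pd
import pytest

from metabostage import (
    ConfigError,
    ValidationError,
    diagnostic_score,
    fit_diagnostic_model,
    fit_logistic,
    lasso_logistic_path,
    lasso_stability_select,
    stepwise_aic_select,
)
from metabostage.selection import DiagnosticModel, stratified_folds


# ----------------------------------------------------------------------
# independent oracle: proximal-gradient (FISTA) L1 logistic


def fista_lasso_logistic(X, y, lam, n_iter=20000, tol=1e-10):
    """Solve (1/n)·logloss + lam·||beta||_1 (intercept unpenalised) by
    accelerated proximal gradient — an implementation independent of the
    coordinate-descent solver under test."""
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    L = np.linalg.norm(Xd, 2) ** 2 / (4.0 * n)
    step = 1.0 / L
    w = np.zeros(p + 1)
    z = w.copy()
    t = 1.0
    for _ in range(n_iter):
        mu = 1.0 / (1.0 + np.exp(-(Xd @ z)))
        grad = Xd.T @ (mu - y) / n
        w_new = z - step * grad
        # soft-threshold all but the intercept
        s = step * lam
        w_new[1:] = np.sign(w_new[1:]) * np.maximum(np.abs(w_new[1:]) - s, 0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = w_new + ((t - 1) / t_new) * (w_new - w)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w, t = w_new, t_new
    return w[0], w[1:]


def _binary_problem(n, p, rng, beta=None):
    X = rng.standard_normal((n, p))
    if beta is None:
        beta = np.zeros(p)
        beta[: min(3, p)] = [1.0, -0.8, 0.5][: min(3, p)]
    eta = X @ beta - 0.2
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


# ----------------------------------------------------------------------
# penalised path


def test_path_zero_at_lambda_max(rng):
    X, y = _binary_problem(200, 8, rng)
    lambdas, intercepts, coefs = lasso_logistic_path(X, y)
    assert np.all(coefs[0] == 0.0)
    ybar = y.mean()
    assert intercepts[0] == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-6)
    # the grid descends and the model grows along it
    assert np.all(np.diff(lambdas) < 0)
    nnz = (coefs != 0).sum(axis=1)
    assert nnz[-1] >= nnz[0]


def test_path_matches_proximal_gradient_oracle(rng):
    X, y = _binary_problem(150, 6, rng)
    lam_grid = np.array([0.1, 0.05, 0.02, 0.01])
    _, intercepts, coefs = lasso_logistic_path(X, y, lambdas=lam_grid)
    for i, lam in enumerate(lam_grid):
        b0_ref, b_ref = fista_lasso_logistic(X, y, lam)
        np.testing.assert_allclose(coefs[i], b_ref, atol=2e-5)
        assert intercepts[i] == pytest.approx(b0_ref, abs=2e-5)


def test_path_oracle_support_recovery(rng):
    # at moderate penalty only genuinely informative features enter
    beta = np.r_[1.5, -1.2, np.zeros(8)]
    X, y = _binary_problem(400, 10, rng, beta=beta)
    _, _, coefs = lasso_logistic_path(X, y, lambdas=np.array([0.08]))
    support = np.flatnonzero(coefs[0])
    assert set(support) <= {0, 1} and len(support) >= 1
    b0_ref, b_ref = fista_lasso_logistic(X, y, 0.08)
    np.testing.assert_allclose(coefs[0], b_ref, atol=2e-5)


def test_path_exact_zeros(rng):
    X, y = _binary_problem(100, 12, rng)
    _, _, coefs = lasso_logistic_path(X, y)
    # genuine sparsity: zeros are exact, not tiny floats
    assert coefs[coefs != 0].size + (coefs == 0).sum() == coefs.size
    assert np.min(np.abs(coefs[coefs != 0])) > 1e-8


# ----------------------------------------------------------------------
# stratified folds


def test_stratified_folds_partition(rng):
    y = np.r_[np.ones(23), np.zeros(37)]
    folds = stratified_folds(y, 5, rng)
    all_idx = np.sort(np.concatenate(folds))
    assert np.array_equal(all_idx, np.arange(60))
    for f in folds:
        assert 0 < y[f].sum() < len(f)  # both classes in every fold


def test_stratified_folds_class_too_small(rng):
    y = np.r_[np.ones(3), np.zeros(50)]
    with pytest.raises(ValidationError, match="cannot build"):
        stratified_folds(y, 5, rng)


# ----------------------------------------------------------------------
# stability selection


def _selection_problem(rng, n=200, n_true=2, n_null=10, effect=1.2):
    X = rng.standard_normal((n, n_true + n_null))
    eta = effect * X[:, :n_true].sum(axis=1)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    cols = [f"T{i}" for i in range(n_true)] + [
        f"N{i}" for i in range(n_null)
    ]
    return pd.DataFrame(X, columns=cols), y


def test_stability_selection_recovers_planted(rng):
    X, y = _selection_problem(rng)
    res = lasso_stability_select(
        X, y, k_folds=5, iterations=20, freq_threshold=10, seed=1
    )
    assert set(res.selected) >= {"T0", "T1"}
    t = res.table.set_index("feature")
    assert t.loc["T0", "frequency"] == 20
    # averaged coefficients carry the planted sign
    assert t.loc["T0", "mean_coefficient"] > 0
    assert (t["frequency"] <= res.iterations).all()


def test_stability_selection_deterministic(rng):
    X, y = _selection_problem(rng)
    a = lasso_stability_select(X, y, iterations=8, freq_threshold=4, seed=7)
    b = lasso_stability_select(X, y, iterations=8, freq_threshold=4, seed=7)
    pd.testing.assert_frame_equal(a.table, b.table)
    c = lasso_stability_select(X, y, iterations=8, freq_threshold=4, seed=8)
    assert not a.table.equals(c.table) or a.selected == c.selected


def test_stability_selection_column_permutation_invariant(rng):
    X, y = _selection_problem(rng)
    perm = list(reversed(X.columns))
    a = lasso_stability_select(X, y, iterations=6, freq_threshold=3, seed=3)
    b = lasso_stability_select(
        X[perm], y, iterations=6, freq_threshold=3, seed=3
    )
    ta = a.table.set_index("feature").sort_index()
    tb = b.table.set_index("feature").sort_index()
    pd.testing.assert_frame_equal(ta, tb)


def test_stability_selection_threshold_monotone(rng):
    X, y = _selection_problem(rng)
    res = lasso_stability_select(X, y, iterations=10, freq_threshold=2, seed=5)
    low = set(res.selected)
    res.frequency_threshold = 8
    assert set(res.selected) <= low


def test_stability_selection_validation(rng):
    X, y = _selection_problem(rng, n=60)
    with pytest.raises(ConfigError, match="rule"):
        lasso_stability_select(X, y, rule="2se")
    with pytest.raises(ConfigError, match="exceed"):
        lasso_stability_select(X, y, iterations=10, freq_threshold=11)
    with pytest.raises(ValidationError, match="binary"):
        lasso_stability_select(X, np.arange(60), iterations=2,
                               freq_threshold=1)


# ----------------------------------------------------------------------
# stepwise AIC


def test_stepwise_selects_informative_variable(rng):
    n = 300
    X = pd.DataFrame(
        {
            "signal": rng.standard_normal(n),
            "noise1": rng.standard_normal(n),
            "noise2": rng.standard_normal(n),
        }
    )
    eta = 1.5 * X["signal"].to_numpy()
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    res = stepwise_aic_select(X, y, folds=5, repeats=2, seed=1)
    assert "signal" in res.selected
    assert res.frequencies["signal"] == 1.0
    assert res.n_partitions == 10


def test_stepwise_rejects_all_noise_mostly(rng):
    n = 250
    X = pd.DataFrame(rng.standard_normal((n, 4)),
                     columns=[f"n{i}" for i in range(4)])
    y = (rng.random(n) < 0.5).astype(float)
    res = stepwise_aic_select(X, y, folds=5, repeats=2, seed=2)
    # AIC admits a chance-correlated noise variable at roughly the
    # p < 0.16 level, so allow at most one through on a fixed cohort
    assert len(res.selected) <= 1
    assert (res.frequencies <= 1.0).all() and (res.frequencies >= 0.0).all()


def test_stepwise_rejects_incomplete_candidates(rng):
    X = pd.DataFrame({"a": [1.0, np.nan, 3.0, 2.0]})
    with pytest.raises(ValidationError, match="complete-case"):
        stepwise_aic_select(X, [0, 1, 0, 1])


# ----------------------------------------------------------------------
# diagnostic model + score


def test_diagnostic_score_worked_values():
    m = DiagnosticModel(intercept=0.0, coefficients={})
    assert diagnostic_score(m, {}) == 0.5
    m = DiagnosticModel(intercept=float(np.log(3.0)), coefficients={})
    assert diagnostic_score(m, {}) == pytest.approx(0.75, abs=1e-12)
    m = DiagnosticModel(intercept=0.0, coefficients={"x": 1.0})
    assert diagnostic_score(m, {"x": np.log(3.0)}) == pytest.approx(
        0.75, abs=1e-12
    )


def test_diagnostic_score_overflow_safe():
    m = DiagnosticModel(intercept=0.0, coefficients={"x": 1.0})
    hi = diagnostic_score(m, {"x": 1e6})
    lo = diagnostic_score(m, {"x": -1e6})
    assert hi == pytest.approx(1.0) and np.isfinite(hi)
    assert lo == pytest.approx(0.0) and np.isfinite(lo)


def test_diagnostic_score_applies_scaling():
    m = DiagnosticModel(
        intercept=-1.0, coefficients={"age": 0.5},
        scaling={"age": (63.0, 9.0)},
    )
    lp = -1.0 + 0.5 * (72.0 - 63.0) / 9.0
    assert diagnostic_score(m, {"age": 72.0}) == pytest.approx(
        1 / (1 + np.exp(-lp)), abs=1e-12
    )


def test_diagnostic_score_missing_variable_errors():
    m = DiagnosticModel(intercept=0.0, coefficients={"x": 1.0})
    with pytest.raises(ValidationError, match="missing model variable"):
        diagnostic_score(m, {"y": 1.0})
    with pytest.raises(ValidationError, match="missing model variable"):
        diagnostic_score(m, {"x": np.nan})


def test_fit_diagnostic_model_matches_irls(rng):
    n = 200
    X = pd.DataFrame(
        {"a": rng.standard_normal(n), "b": rng.standard_normal(n)}
    )
    eta = 0.8 * X["a"].to_numpy() - 0.5
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    model = fit_diagnostic_model(X, y, contrast="MI-vs-UA")
    ref = fit_logistic(
        np.column_stack([np.ones(n), X.to_numpy()]), y
    )
    assert model.intercept == pytest.approx(ref.coef[0], abs=1e-10)
    assert model.coefficients["a"] == pytest.approx(ref.coef[1], abs=1e-10)
    assert model.contrast == "MI-vs-UA"
    # vectorised predict agrees with per-row scoring
    preds = model.predict(X.iloc[:5])
    expected = [diagnostic_score(model, X.iloc[i]) for i in range(5)]
    np.testing.assert_allclose(preds, expected, atol=1e-12)


def test_fit_diagnostic_model_empty_set():
    with pytest.raises(ValidationError, match="empty"):
        fit_diagnostic_model(pd.DataFrame(index=[0, 1]), [0, 1])


def test_fit_diagnostic_model_warns_on_separation():
    x = np.r_[np.linspace(-2, -0.1, 15), np.linspace(0.1, 2, 15)]
    y = (x > 0).astype(float)
    with pytest.warns(UserWarning, match="separation"):
        model = fit_diagnostic_model(pd.DataFrame({"x": x}), y)
    assert model.separation
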