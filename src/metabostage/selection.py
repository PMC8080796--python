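"""Diagnostic-model building: stepwise-AIC selection of traditional risk
factors, LASSO stability selection of metabolic markers, and the
combined logistic diagnostic score.

Three models discriminate a stage contrast (e.g. MI vs UA):

* the *traditional* model — bidirectional stepwise logistic selection
  minimising AIC over the conventional risk-factor pool, run on every
  training partition of a repeated cross-validation and aggregated by
  majority inclusion;
* the *metabolic* model — L1-penalised (LASSO) logistic regression over
  the nominally significant features, with the penalty chosen per
  iteration by cross-validated binomial deviance at the "1-se" lambda,
  repeated over many random fold splits; features kept in more than
  half the iterations form the model;
* the *combined* model — the same stability selection run on the union
  of significant features and the risk-factor pool, so metabolites and
  risk factors compete under the same penalty.

The LASSO path solver is a glmnet-style coordinate descent (IRLS outer
loop, soft-thresholding inner loop, warm starts along a log-spaced
penalty grid, unpenalised intercept) compiled with numba.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .association import LogisticFit, fit_logistic
from .errors import ConfigError, ValidationError


# ----------------------------------------------------------------------
# penalised path solver


@njit(cache=True)
def _cd_sweep(X, w, r, beta, lam, h, active_only, active):  # pragma: no cover
    """One pass of cyclic coordinate soft-threshold updates; returns the
    largest coefficient change."""
    n, p = X.shape
    delta = 0.0
    for j in range(p):
        if active_only and not active[j]:
            continue
        gj = 0.0
        for i in range(n):
            gj += w[i] * X[i, j] * r[i]
        gj = gj / n + h[j] * beta[j]
        if gj > lam:
            bnew = (gj - lam) / h[j]
        elif gj < -lam:
            bnew = (gj + lam) / h[j]
        else:
            bnew = 0.0
        diff = bnew - beta[j]
        if diff != 0.0:
            beta[j] = bnew
            for i in range(n):
                r[i] -= X[i, j] * diff
            if abs(diff) > delta:
                delta = abs(diff)
        if beta[j] != 0.0:
            active[j] = True
    return delta


@njit(cache=True)
def _cd_path(X, y, lambdas, tol, max_outer, max_inner):  # pragma: no cover
    n, p = X.shape
    coefs = np.zeros((lambdas.shape[0], p))
    intercepts = np.zeros(lambdas.shape[0])
    ybar = y.mean()
    b0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    eta = np.full(n, b0)
    h = np.zeros(p)
    active = np.zeros(p, dtype=np.bool_)
    null_dev = 0.0
    for li in range(lambdas.shape[0]):
        lam = lambdas[li]
        for _outer in range(max_outer):
            # IRLS working response at the current estimate
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            for i in range(n):
                if w[i] < 1e-5:
                    w[i] = 1e-5
            z = eta + (y - mu) / w
            r = z - eta
            wsum = w.sum()
            for j in range(p):
                hj = 0.0
                for i in range(n):
                    hj += w[i] * X[i, j] * X[i, j]
                h[j] = hj / n
            for j in range(p):
                active[j] = beta[j] != 0.0
            delta_outer = 0.0
            for _cycle in range(max_inner):
                # full sweep refreshes the active set
                num = 0.0
                for i in range(n):
                    num += w[i] * r[i]
                db0 = num / wsum
                b0 += db0
                for i in range(n):
                    r[i] -= db0
                delta = _cd_sweep(X, w, r, beta, lam, h, False, active)
                if abs(db0) > delta:
                    delta = abs(db0)
                if delta > delta_outer:
                    delta_outer = delta
                if delta < tol:
                    break
                # iterate on the active set until stable
                for _a in range(max_inner):
                    num = 0.0
                    for i in range(n):
                        num += w[i] * r[i]
                    db0 = num / wsum
                    b0 += db0
                    for i in range(n):
                        r[i] -= db0
                    d2 = _cd_sweep(X, w, r, beta, lam, h, True, active)
                    if max(d2, abs(db0)) < tol:
                        break
            eta = z - r
            if delta_outer < tol:
                break
        coefs[li] = beta
        intercepts[li] = b0
        # stop once the fit saturates (deviance explained ~ 1), as the
        # remaining, smaller penalties only grow coefficients without
        # changing the CV picture near the optimum
        dev = 0.0
        for i in range(n):
            mu_i = 1.0 / (1.0 + np.exp(-eta[i]))
            if mu_i < 1e-10:
                mu_i = 1e-10
            elif mu_i > 1.0 - 1e-10:
                mu_i = 1.0 - 1e-10
            dev -= 2.0 * (y[i] * np.log(mu_i) + (1.0 - y[i]) * np.log(1.0 - mu_i))
        if li == 0:
            null_dev = dev
        elif null_dev > 0.0 and dev < 0.02 * null_dev:
            return intercepts, coefs, li + 1
    return intercepts, coefs, lambdas.shape[0]


def lasso_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """L1-penalised logistic path over a descending penalty grid.

    Returns ``(lambdas, intercepts, coefs)`` where ``coefs`` is
    (n_lambda × p) with exact zeros.  ``lambda_max`` — the smallest
    penalty that zeroes every coefficient — is ``max_j |x_j'(y − ȳ)|/n``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    auto_grid = lambdas is None
    if auto_grid:
        lam_max = float(np.max(np.abs(X.T @ (y - y.mean()))) / n)
        lam_max = max(lam_max, 1e-10)
        lambdas = np.logspace(
            np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambda
        )
    lambdas = np.asarray(lambdas, dtype=np.float64)
    intercepts, coefs, n_valid = _cd_path(X, y, lambdas, tol, 25, 200)
    coefs[np.abs(coefs) < 1e-8] = 0.0  # guard against numerical dust
    if n_valid < len(lambdas):
        if auto_grid:
            # the grid ends where ~98% of the null deviance is explained:
            # smaller penalties only inflate a saturated fit
            return lambdas[:n_valid], intercepts[:n_valid], coefs[:n_valid]
        # explicit grid (CV fold fits): hold the saturated solution
        intercepts[n_valid:] = intercepts[n_valid - 1]
        coefs[n_valid:] = coefs[n_valid - 1]
    return lambdas, intercepts, coefs


def stratified_folds(y: np.ndarray, k: int, rng) -> list[np.ndarray]:
    """Random class-stratified fold memberships (test indices per fold)."""
    y = np.asarray(y)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValidationError(
                f"class {cls} has {len(idx)} samples; cannot build {k} "
                "folds with both classes in every fold"
            )
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].extend(chunk.tolist())
    return [np.sort(np.array(f)) for f in folds]


def _binomial_deviance(y, p):
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class SelectionResult:
    """Per-candidate inclusion frequency and averaged coefficient."""

    table: pd.DataFrame  # feature, frequency, mean_coefficient
    iterations: int
    frequency_threshold: int
    rule: str = "1se"

    @property
    def selected(self) -> list[str]:
        t = self.table
        return t.loc[t["frequency"] > self.frequency_threshold, "feature"].tolist()

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, iterations: int | None = None,
        frequency_threshold: int | None = None,
    ) -> "SelectionResult":
        its = iterations or int(frame["frequency"].max())
        return cls(
            frame, its,
            frequency_threshold if frequency_threshold is not None else its // 2,
        )


def lasso_stability_select(
    X: pd.DataFrame,
    y,
    k_folds: int = 5,
    iterations: int = 200,
    rule: str = "1se",
    freq_threshold: int = 100,
    seed: int = 0,
    *,
    n_lambda: int = 100,
    zero_mean_coefficient: bool = False,
) -> SelectionResult:
    """Stability selection over repeated cross-validated LASSO fits.

    Each iteration draws a fresh stratified ``k_folds`` split, traces
    the cross-validated binomial-deviance curve over a shared
    log-spaced penalty grid, picks the penalty by ``rule`` ("min" or
    the one-standard-error "1se"), and records which features are
    non-zero in the full-data fit at that penalty.  Mean coefficients
    average over the iterations where the feature was selected (set
    ``zero_mean_coefficient`` to average zeros in instead).
    """
    if rule not in ("min", "1se"):
        raise ConfigError("rule must be 'min' or '1se'")
    if freq_threshold > iterations:
        raise ConfigError("freq_threshold cannot exceed iterations")
    X = pd.DataFrame(X)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ValidationError("y must be binary 0/1")
    rng = np.random.default_rng(seed)
    lambdas, full_int, full_coefs = lasso_logistic_path(
        Xv, yv, n_lambda=n_lambda
    )
    nl = len(lambdas)
    freq = np.zeros(len(names), dtype=int)
    coef_sum = np.zeros(len(names))
    coef_cnt = np.zeros(len(names), dtype=int)
    for _ in range(iterations):
        folds = stratified_folds(yv, k_folds, rng)
        dev = np.zeros((k_folds, nl))
        for f, test_idx in enumerate(folds):
            mask = np.ones(len(yv), dtype=bool)
            mask[test_idx] = False
            _, b0s, betas = lasso_logistic_path(
                Xv[mask], yv[mask], lambdas=lambdas
            )
            eta = b0s[:, None] + betas @ Xv[test_idx].T
            p = 1.0 / (1.0 + np.exp(-eta))
            yt = yv[test_idx]
            for li in range(nl):
                dev[f, li] = _binomial_deviance(yt, p[li])
        cv_mean = dev.mean(axis=0)
        cv_se = dev.std(axis=0, ddof=1) / np.sqrt(k_folds)
        i_min = int(np.argmin(cv_mean))
        if rule == "min":
            chosen = i_min
        else:
            # largest penalty within one SE of the minimum
            ok = cv_mean <= cv_mean[i_min] + cv_se[i_min]
            chosen = int(np.flatnonzero(ok)[0])  # grid descends from λ_max
        support = full_coefs[chosen] != 0
        freq += support
        coef_sum += full_coefs[chosen]
        coef_cnt += support
    if zero_mean_coefficient:
        mean_coef = coef_sum / iterations
    else:
        with np.errstate(invalid="ignore"):
            mean_coef = np.where(coef_cnt > 0, coef_sum / np.maximum(coef_cnt, 1), 0.0)
    table = pd.DataFrame(
        {"feature": names, "frequency": freq, "mean_coefficient": mean_coef}
    )
    return SelectionResult(table, iterations, freq_threshold, rule)


# ----------------------------------------------------------------------
# stepwise AIC


@dataclass
class StepwiseResult:
    selected: list[str]
    frequencies: pd.Series  # variable -> fraction of partitions selected
    n_partitions: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.frequencies.index,
                "frequency": self.frequencies.to_numpy(),
            }
        )


def _stepwise_once(X: pd.DataFrame, y: np.ndarray) -> list[str] | None:
    """Bidirectional stepwise logistic selection minimising AIC,
    starting from the intercept-only model.  None on non-convergence."""
    names = list(X.columns)
    current: list[str] = []

    def aic_of(varset):
        design = np.column_stack(
            [np.ones(len(y))] + [X[v].to_numpy(float) for v in varset]
        )
        fit = fit_logistic(design, y)
        if fit.rank_deficient or not np.isfinite(fit.loglik):
            return np.inf, fit
        return fit.aic, fit

    best_aic, fit0 = aic_of(current)
    if not np.isfinite(best_aic):
        return None
    while True:
        moves = []
        for v in names:
            if v not in current:
                moves.append(current + [v])
        for v in current:
            moves.append([w for w in current if w != v])
        best_move, best_move_aic = None, best_aic
        for cand in moves:
            a, _ = aic_of(cand)
            if a < best_move_aic - 1e-10:
                best_move, best_move_aic = cand, a
        if best_move is None:
            return current
        current, best_aic = best_move, best_move_aic


def stepwise_aic_select(
    candidates: pd.DataFrame,
    y,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> StepwiseResult:
    """Repeated cross-validated bidirectional stepwise-AIC selection.

    For each of ``repeats × folds`` training partitions a full
    bidirectional stepwise search is run; a variable enters the final
    set when selected in more than half of the partitions.
    """
    candidates = pd.DataFrame(candidates)
    if candidates.isna().any().any():
        raise ValidationError("candidate matrix must be complete-case")
    yv = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    counts = pd.Series(0, index=candidates.columns, dtype=float)
    n_parts = 0
    for _ in range(repeats):
        fold_idx = stratified_folds(yv, folds, rng)
        for test_idx in fold_idx:
            mask = np.ones(len(yv), dtype=bool)
            mask[test_idx] = False
            sel = _stepwise_once(candidates.loc[mask], yv[mask])
            if sel is None:
                warnings.warn("stepwise partition skipped: non-convergence")
                continue
            n_parts += 1
            counts[sel] += 1
    if n_parts == 0:
        raise ValidationError("no stepwise partition converged")
    freq = counts / n_parts
    selected = list(freq.index[freq > 0.5])
    return StepwiseResult(selected, freq, n_parts)


# ----------------------------------------------------------------------
# final diagnostic model


@dataclass
class DiagnosticModel:
    """Unpenalised logistic model over the selected variables.

    Stores the feature scaling (centre, scale) applied during training
    so new raw samples can be scored on the same footing.
    """

    intercept: float
    coefficients: dict  # variable -> coefficient
    contrast: str = ""
    scaling: dict = field(default_factory=dict)  # variable -> (center, scale)
    separation: bool = False

    @property
    def variables(self) -> list[str]:
        return list(self.coefficients)

    def linear_predictor(self, x) -> float:
        lp = self.intercept
        for name, coef in self.coefficients.items():
            if name not in x or pd.isna(x[name]):
                raise ValidationError(f"missing model variable {name!r}")
            v = float(x[name])
            if name in self.scaling:
                c, s = self.scaling[name]
                v = (v - c) / s
            lp += coef * v
        return lp

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.array(
            [diagnostic_score(self, row) for _, row in X.iterrows()]
        )

    def to_json_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "contrast": self.contrast,
            "scaling": {k: [float(c), float(s)] for k, (c, s) in self.scaling.items()},
            "separation": self.separation,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "DiagnosticModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients=dict(d["coefficients"]),
            contrast=d.get("contrast", ""),
            scaling={k: tuple(v) for k, v in d.get("scaling", {}).items()},
            separation=bool(d.get("separation", False)),
        )


def fit_diagnostic_model(
    X_selected: pd.DataFrame,
    y,
    contrast: str = "",
    scaling: dict | None = None,
) -> DiagnosticModel:
    """Maximum-likelihood logistic refit on the selected variables."""
    X_selected = pd.DataFrame(X_selected)
    if X_selected.shape[1] == 0:
        raise ValidationError("selected variable set is empty")
    yv = np.asarray(y, dtype=float)
    design = np.column_stack(
        [np.ones(len(yv)), X_selected.to_numpy(dtype=float)]
    )
    fit = fit_logistic(design, yv)
    if fit.separation:
        warnings.warn("separation detected in diagnostic-model refit")
    return DiagnosticModel(
        intercept=float(fit.coef[0]),
        coefficients=dict(zip(X_selected.columns, map(float, fit.coef[1:]))),
        contrast=contrast,
        scaling=scaling or {},
        separation=fit.separation,
    )


def diagnostic_score(model: DiagnosticModel, x) -> float:
    """Probability 1 / (1 + exp(−(intercept + Σ coef·x))), overflow-safe."""
    lp = model.linear_predictor(x)
    if lp >= 0:
        return float(1.0 / (1.0 + np.exp(-min(lp, 700.0))))
    e = np.exp(max(lp, -700.0))
    return float(e / (1.0 + e))
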