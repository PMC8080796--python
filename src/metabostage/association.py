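"""Covariate-adjusted per-feature association scans.

Each metabolite is tested one at a time: logistic regression of a stage
contrast (UA vs SCAD, MI vs UA) or linear regression of a numeric
severity trait (SYNTAX score, hs-CRP, cTnI, …) on the pareto-scaled
feature plus a fixed covariate set (age, sex, hypertension, diabetes,
smoking, LDLC, HDLC, TG).  Rows with missing covariates are omitted.
Estimates are reported with Wald standard errors, odds ratios and 95%
confidence intervals; Benjamini–Hochberg FDR is reported across the
scan, but downstream selection gates on nominal p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .containers import ADJUSTMENT_COVARIATES, FeatureMatrix, SampleMetadata
from .errors import ConfigError, ValidationError

CONTRASTS = {"UA-vs-SCAD": ("SCAD", "UA"), "MI-vs-UA": ("UA", "MI")}


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald covariance."""

    coef: np.ndarray
    cov: np.ndarray
    converged: bool
    separation: bool = False
    rank_deficient: bool = False
    n_iter: int = 0
    loglik: float = np.nan

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def aic(self) -> float:
        return 2 * len(self.coef) - 2 * self.loglik


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _loglik(y, p):
    eps = 1e-12
    return float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Newton/IRLS logistic regression.

    ``X`` is the full design matrix including any intercept column.
    Convergence is declared when the largest absolute score component
    falls below ``tol``.  Quasi-complete separation (coefficients
    diverging without the score vanishing) is flagged rather than
    raised, as is a rank-deficient design.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValidationError("y has a single class")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        return LogisticFit(
            np.full(p, np.nan), np.full((p, p), np.nan),
            converged=False, rank_deficient=True,
        )
    beta = np.zeros(p)
    ll = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = _sigmoid(eta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            break
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            return LogisticFit(
                beta, np.full((p, p), np.nan),
                converged=False, rank_deficient=True, n_iter=it,
            )
        # step-halving keeps the likelihood monotone
        new_ll = -np.inf
        for _ in range(30):
            cand = beta + step
            new_ll = _loglik(y, _sigmoid(X @ cand))
            if new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        ll = new_ll
    eta = X @ beta
    mu = _sigmoid(eta)
    score = X.T @ (y - mu)
    converged = bool(np.max(np.abs(score)) < max(tol, 1e-6))
    separation = bool(np.max(np.abs(beta)) > 30)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return LogisticFit(
        beta, cov, converged=converged, separation=separation,
        n_iter=it if max_iter else 0, loglik=_loglik(y, mu),
    )


def _as_frame(features) -> pd.DataFrame:
    if isinstance(features, FeatureMatrix):
        return features.study_values()
    return pd.DataFrame(features)


def _complete_design(
    feats: pd.DataFrame, md: SampleMetadata, covariates, rows
) -> tuple[pd.DataFrame, pd.DataFrame]:
    cov = md.covariates(covariates).reindex(rows)
    feats = feats.reindex(rows)
    keep = cov.notna().all(axis=1) & feats.notna().all(axis=1)
    return feats.loc[keep], cov.loc[keep]


def adjusted_logistic_scan(
    features,
    metadata: SampleMetadata,
    contrast: str = "MI-vs-UA",
    covariates=ADJUSTMENT_COVARIATES,
) -> pd.DataFrame:
    """Per-feature adjusted logistic regression for one stage contrast.

    Fits ``stage ~ feature + covariates`` independently per feature on
    the complete-case rows of the two contrasted stages and returns a
    table of per-pareto-unit log-odds estimates, ORs, 95% CIs, Wald p
    and BH FDR.  Features flagged for separation or rank deficiency get
    NA inference columns.
    """
    if contrast not in CONTRASTS:
        raise ConfigError(
            f"unknown contrast {contrast!r}; use one of {list(CONTRASTS)}"
        )
    ref, case = CONTRASTS[contrast]
    feats = _as_frame(features)
    stage = metadata.stage.reindex(feats.index)
    rows = stage.index[stage.isin([ref, case])]
    feats, cov = _complete_design(feats, metadata, covariates, rows)
    y = (metadata.stage.reindex(feats.index) == case).to_numpy(float)
    covX = cov.to_numpy(float)
    n = len(y)
    base = np.column_stack([np.ones(n), np.zeros(n), covX])
    records = []
    for feat in feats.columns:
        base[:, 1] = feats[feat].to_numpy(float)
        fit = fit_logistic(base, y)
        bad = fit.rank_deficient or fit.separation or not fit.converged
        if bad:
            records.append(
                {"feature": feat, "estimate": np.nan, "se": np.nan,
                 "OR": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                 "p": np.nan, "n": n,
                 "flag": "rank_deficient" if fit.rank_deficient
                 else "separation"}
            )
            continue
        est, se = fit.coef[1], fit.se[1]
        z = est / se
        records.append(
            {
                "feature": feat,
                "estimate": est,
                "se": se,
                "OR": float(np.exp(est)),
                "ci_low": float(np.exp(est - 1.959963984540054 * se)),
                "ci_high": float(np.exp(est + 1.959963984540054 * se)),
                "p": float(2 * norm.sf(abs(z))),
                "n": n,
                "flag": "",
            }
        )
    table = pd.DataFrame(records)
    ok = table["p"].notna()
    table["fdr"] = np.nan
    if ok.any():
        table.loc[ok, "fdr"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    table.attrs["contrast"] = contrast
    table.attrs["covariates"] = list(covariates)
    return table


LOG_TRANSFORMED_TRAITS = ("hs_CRP", "cTnI")


def adjusted_linear_scan(
    features,
    metadata: SampleMetadata,
    trait: str,
    covariates=ADJUSTMENT_COVARIATES,
    log_transform: bool | None = None,
) -> pd.DataFrame:
    """Per-feature adjusted linear regression against a severity trait.

    ``trait ~ feature + covariates`` with classical OLS inference.
    Heavily right-skewed markers (hs-CRP, cTnI) are natural-log
    transformed by default, with a half-minimum-positive offset for
    zeros; pass ``log_transform=False`` to disable.
    """
    if trait not in metadata.table.columns:
        raise ConfigError(f"trait {trait!r} not in metadata")
    feats = _as_frame(features)
    t = pd.to_numeric(metadata.table[trait], errors="coerce").reindex(feats.index)
    if log_transform is None:
        log_transform = trait in LOG_TRANSFORMED_TRAITS
    rows = t.index[t.notna()]
    if len(rows) < 3 or t.loc[rows].nunique() == 1:
        raise ValidationError(f"trait {trait!r} is constant or nearly empty")
    feats_c, cov = _complete_design(feats, metadata, covariates, rows)
    yv = t.reindex(feats_c.index).to_numpy(float)
    if log_transform:
        pos_min = np.min(yv[yv > 0]) if np.any(yv > 0) else 1.0
        yv = np.log(yv + 0.5 * pos_min * (yv <= 0))
    n = len(yv)
    covX = cov.to_numpy(float)
    base = np.column_stack([np.ones(n), np.zeros(n), covX])
    p_cols = base.shape[1]
    records = []
    for feat in feats_c.columns:
        base[:, 1] = feats_c[feat].to_numpy(float)
        if np.linalg.matrix_rank(base) < p_cols:
            records.append(
                {"feature": feat, "estimate": np.nan, "se": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                 "n": n, "flag": "rank_deficient"}
            )
            continue
        xtx_inv = np.linalg.inv(base.T @ base)
        beta = xtx_inv @ (base.T @ yv)
        resid = yv - base @ beta
        dof = n - p_cols
        sigma2 = float(resid @ resid) / dof
        se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
        est = float(beta[1])
        from scipy.stats import t as t_dist

        tv = est / se
        records.append(
            {
                "feature": feat,
                "estimate": est,
                "se": se,
                "ci_low": est - t_dist.ppf(0.975, dof) * se,
                "ci_high": est + t_dist.ppf(0.975, dof) * se,
                "p": float(2 * t_dist.sf(abs(tv), dof)),
                "n": n,
                "flag": "",
            }
        )
    table = pd.DataFrame(records)
    ok = table["p"].notna()
    table["fdr"] = np.nan
    if ok.any():
        table.loc[ok, "fdr"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    table.attrs["trait"] = trait
    table.attrs["covariates"] = list(covariates)
    table.attrs["log_transformed"] = bool(log_transform)
    return table


def significant_features(table: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Nominally significant features — the downstream selection pool."""
    return table.loc[table["p"] < alpha, "feature"].tolist()
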