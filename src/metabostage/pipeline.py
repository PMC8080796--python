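"""End-to-end convenience layer: build and compare the three diagnostic
models (traditional, metabolic, combined) for a stage contrast.

These functions wire the lower-level modules together the way the CLI
and the worked examples use them; every step is also available
individually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import CONTRASTS, adjusted_logistic_scan, significant_features
from .containers import (
    AnalysisConfig,
    FeatureMatrix,
    SampleMetadata,
    TRADITIONAL_CANDIDATES,
)
from .errors import ValidationError
from .evaluation import EvaluationReport, evaluate_pair
from .selection import (
    DiagnosticModel,
    SelectionResult,
    StepwiseResult,
    fit_diagnostic_model,
    lasso_stability_select,
    stepwise_aic_select,
)


def contrast_cohort(
    scaled, metadata: SampleMetadata, contrast: str,
    candidates=TRADITIONAL_CANDIDATES,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Complete-case rows of the two contrasted stages.

    Returns ``(features, risk_factors, y)`` aligned on the same rows,
    with ``y = 1`` for the later (more severe) stage.
    """
    ref, case = CONTRASTS[contrast]
    feats = scaled.study_values() if isinstance(scaled, FeatureMatrix) else pd.DataFrame(scaled)
    meta = metadata.table.reindex(feats.index)
    rows = meta.index[meta["stage"].isin([ref, case])]
    risk = meta.loc[rows, list(candidates)]
    keep = risk.notna().all(axis=1) & feats.loc[rows].notna().all(axis=1)
    rows = rows[keep]
    y = (meta.loc[rows, "stage"] == case).to_numpy(float)
    if y.min() == y.max():
        raise ValidationError(f"contrast {contrast} has a single class")
    return feats.loc[rows], meta.loc[rows, list(candidates)], y


def standardize(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Z-score columns; returns the frame and a {name: (center, scale)}
    record for scoring new samples."""
    center = df.mean(axis=0)
    scale = df.std(axis=0, ddof=1).replace(0.0, 1.0)
    z = (df - center) / scale
    scaling = {c: (float(center[c]), float(scale[c])) for c in df.columns}
    return z, scaling


@dataclass
class ModelComparison:
    """Everything produced for one stage contrast."""

    contrast: str
    association: pd.DataFrame
    traditional: DiagnosticModel
    stepwise: StepwiseResult
    metabolic: DiagnosticModel
    metabolic_selection: SelectionResult
    combined: DiagnosticModel
    combined_selection: SelectionResult
    report_combined_vs_traditional: EvaluationReport
    report_metabolic_vs_traditional: EvaluationReport


def build_traditional_model(
    risk: pd.DataFrame, y, config: AnalysisConfig, contrast: str = "",
) -> tuple[DiagnosticModel, StepwiseResult]:
    """Stepwise-AIC risk-factor model over repeated CV partitions."""
    z, scaling = standardize(risk)
    step = stepwise_aic_select(
        z, y, folds=config.cv_folds, repeats=config.stepwise_repeats,
        seed=config.seed,
    )
    if step.selected:
        model = fit_diagnostic_model(
            z[step.selected], y, contrast=contrast,
            scaling={k: scaling[k] for k in step.selected},
        )
    else:  # intercept-only fallback when nothing survives
        prev = float(np.mean(y))
        model = DiagnosticModel(
            intercept=float(np.log(prev / (1 - prev))), coefficients={},
            contrast=contrast,
        )
    return model, step


def build_lasso_model(
    X: pd.DataFrame, y, config: AnalysisConfig, contrast: str = "",
    scaling: dict | None = None, seed_offset: int = 0,
) -> tuple[DiagnosticModel, SelectionResult]:
    """Stability-selected LASSO model refit by plain logistic ML."""
    sel = lasso_stability_select(
        X, y,
        k_folds=config.cv_folds,
        iterations=config.lasso_iterations,
        rule="1se",
        freq_threshold=config.frequency_threshold,
        seed=config.seed + seed_offset,
    )
    chosen = sel.selected
    if not chosen:  # fall back to the most frequently selected feature
        top = sel.table.sort_values(
            ["frequency", "feature"], ascending=[False, True]
        )["feature"].iloc[0]
        chosen = [top]
    model = fit_diagnostic_model(
        X[chosen], y, contrast=contrast,
        scaling={k: scaling[k] for k in chosen if scaling and k in scaling},
    )
    return model, sel


def compare_diagnostic_models(
    scaled,
    metadata: SampleMetadata,
    contrast: str = "MI-vs-UA",
    config: AnalysisConfig | None = None,
    n_boot: int = 2000,
) -> ModelComparison:
    """Build traditional, metabolic and combined models and compare them.

    The metabolic candidate pool is the set of features nominally
    significant (p < 0.05) in the covariate-adjusted logistic scan; the
    combined pool adds the standardized traditional risk factors so
    both kinds of predictor compete inside the same LASSO.
    """
    config = config or AnalysisConfig()
    assoc = adjusted_logistic_scan(scaled, metadata, contrast)
    sig = significant_features(assoc)
    feats, risk, y = contrast_cohort(scaled, metadata, contrast)

    traditional, stepwise = build_traditional_model(
        risk, y, config, contrast
    )
    if not sig:
        raise ValidationError(
            "no nominally significant features for the metabolic model"
        )
    # LASSO competes on z-standardized candidates; the recorded scaling
    # lets the refit models score raw (pareto-unit / raw-covariate) input
    met_z, met_scaling = standardize(feats[sig])
    metabolic, met_sel = build_lasso_model(
        met_z, y, config, contrast, scaling=met_scaling, seed_offset=1
    )
    pool, pool_scaling = standardize(pd.concat([feats[sig], risk], axis=1))
    combined, comb_sel = build_lasso_model(
        pool, y, config, contrast, scaling=pool_scaling, seed_offset=2
    )

    p_trad = traditional.predict(risk)
    p_met = metabolic.predict(feats)
    p_comb = combined.predict(pd.concat([feats, risk], axis=1))
    rep_comb = evaluate_pair(
        p_trad, p_comb, y,
        comparison=f"combined-vs-traditional ({contrast})",
        n_boot=n_boot, seed=config.seed,
    )
    rep_met = evaluate_pair(
        p_trad, p_met, y,
        comparison=f"metabolic-vs-traditional ({contrast})",
        n_boot=n_boot, seed=config.seed,
    )
    return ModelComparison(
        contrast=contrast,
        association=assoc,
        traditional=traditional,
        stepwise=stepwise,
        metabolic=metabolic,
        metabolic_selection=met_sel,
        combined=combined,
        combined_selection=comb_sel,
        report_combined_vs_traditional=rep_comb,
        report_metabolic_vs_traditional=rep_met,
    )
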