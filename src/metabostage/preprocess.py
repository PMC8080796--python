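"""Preprocessing: QC missing-rate filter, minimum-value imputation,
QC-RLSC drift correction and pareto scaling.

The pipeline order is fixed — filter → impute → QC-RLSC → pareto — and
mirrors routine practice for pooled-QC targeted metabolomics: features
that drop out in more than half of the QC injections are unreliable and
removed; remaining zero-intensity cells are taken as below-detection and
replaced by the feature's observed minimum; a robust LOESS trend fitted
to the QC injections is divided out per feature and batch; finally
features are mean-centred and scaled by the square root of their
standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import FeatureMatrix
from .errors import ValidationError


@dataclass
class PreprocessReport:
    """What each preprocessing step did, feature by feature."""

    removed_features: dict = field(default_factory=dict)  # id -> QC missing frac
    imputed_counts: dict = field(default_factory=dict)  # id -> cells imputed
    qc_rsd_before: dict = field(default_factory=dict)  # id -> RSD over QC
    qc_rsd_after: dict = field(default_factory=dict)
    fallback_features: list = field(default_factory=list)  # median-scaled
    span_used: float | None = None
    #: LOESS trend is extended as a constant beyond the first/last QC
    extrapolation: str = "nearest-fitted-value"

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        self.removed_features.update(other.removed_features)
        self.imputed_counts.update(other.imputed_counts)
        self.qc_rsd_before.update(other.qc_rsd_before)
        self.qc_rsd_after.update(other.qc_rsd_after)
        self.fallback_features += other.fallback_features
        if other.span_used is not None:
            self.span_used = other.span_used
        return self

    def to_json_dict(self) -> dict:
        return {
            "removed_features": {k: float(v) for k, v in self.removed_features.items()},
            "imputed_counts": {k: int(v) for k, v in self.imputed_counts.items()},
            "qc_rsd_before": {k: float(v) for k, v in self.qc_rsd_before.items()},
            "qc_rsd_after": {k: float(v) for k, v in self.qc_rsd_after.items()},
            "fallback_features": list(self.fallback_features),
            "span_used": self.span_used,
            "extrapolation": self.extrapolation,
        }


def qc_rsd(fm: FeatureMatrix) -> pd.Series:
    """Relative standard deviation per feature over the QC injections."""
    qc = fm.qc_values()
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    return sd / mean.where(mean != 0, np.nan)


def filter_by_qc_missing_rate(
    fm: FeatureMatrix, threshold: float = 0.5
) -> tuple[FeatureMatrix, PreprocessReport]:
    """Drop features missing (zero intensity) in more than ``threshold``
    of the QC injections; recode remaining zeros as explicit NaN.

    Study rows are untouched apart from the zero → NaN recoding, which
    prevents later steps from confusing missingness with true zeros.
    """
    if int(fm.is_qc.sum()) < 1:
        raise ValidationError("QC missing-rate filter needs >= 1 QC injection")
    qc = fm.qc_values().to_numpy()
    missing_frac = np.mean((qc == 0) | np.isnan(qc), axis=0)
    drop = missing_frac > threshold
    report = PreprocessReport(
        removed_features={
            f: float(missing_frac[j])
            for j, f in enumerate(fm.feature_ids)
            if drop[j]
        }
    )
    kept = [f for j, f in enumerate(fm.feature_ids) if not drop[j]]
    vals = fm.values.loc[:, kept].copy()
    vals = vals.mask(vals == 0, np.nan)
    out = fm.replace_values(vals, allow_missing=True)
    return out, report


def impute_min(fm: FeatureMatrix) -> tuple[FeatureMatrix, PreprocessReport]:
    """Replace each missing cell with its feature's observed minimum."""
    vals = fm.values.copy()
    vals = vals.mask(vals == 0, np.nan)  # raw zeros also count as missing
    n_missing = vals.isna().sum(axis=0)
    all_missing = n_missing == len(vals)
    if all_missing.any():
        raise ValidationError(
            "feature(s) with no observed value: "
            f"{vals.columns[all_missing].tolist()}; filter them first"
        )
    filled = vals.fillna(vals.min(axis=0))
    report = PreprocessReport(
        imputed_counts={
            f: int(n_missing[f]) for f in vals.columns if n_missing[f] > 0
        }
    )
    return fm.replace_values(filled), report


def _loess_trend(x_qc, y_qc, x_all, span: float) -> np.ndarray:
    """Robust local-linear trend through the QC points, evaluated at all
    injections; constant (nearest fitted value) beyond the QC range."""
    fitted = lowess(
        y_qc, x_qc, frac=span, it=3, return_sorted=True
    )
    return np.interp(x_all, fitted[:, 0], fitted[:, 1])


def qc_rlsc_correct(
    fm: FeatureMatrix, span: float = 0.75
) -> tuple[FeatureMatrix, PreprocessReport]:
    """QC-based robust LOESS signal correction, per feature and batch.

    For each feature within each analytical batch, a robust
    (iteratively reweighted, 3 passes) local-linear regression of the
    pooled-QC abundances on injection order is fitted with the given
    span, interpolated to every injection, and divided out:
    ``corrected = raw × median(QC) / trend``.  The trend is floored at a
    small positive value; if it still dips non-positive the feature
    falls back to flat batch-median scaling with a warning.  Batches are
    corrected independently.
    """
    report = PreprocessReport(span_used=span)
    report.qc_rsd_before = qc_rsd(fm).to_dict()
    vals = fm.values.to_numpy().copy()
    order = fm.injection_order.astype(float)
    for batch in fm.batches():
        in_batch = fm.batch_id == batch
        qc_rows = in_batch & fm.is_qc
        if qc_rows.sum() < 3:
            raise ValidationError(
                f"batch {batch!r} has {int(qc_rows.sum())} QC injections; "
                "QC-RLSC needs at least 3 per batch"
            )
        x_qc = order[qc_rows]
        x_all = order[in_batch]
        for j, feat in enumerate(fm.feature_ids):
            y_qc = vals[qc_rows, j]
            med = float(np.median(y_qc))
            trend = _loess_trend(x_qc, y_qc, x_all, span)
            floor = 1e-6 * max(abs(med), 1.0)
            if np.any(trend <= 0):
                warnings.warn(
                    f"non-positive LOESS trend for feature {feat} in batch "
                    f"{batch!r}; falling back to batch-median scaling"
                )
                report.fallback_features.append(feat)
                trend = np.full_like(trend, max(med, floor))
            trend = np.maximum(trend, floor)
            vals[in_batch, j] = vals[in_batch, j] * med / trend
    out = fm.replace_values(
        pd.DataFrame(vals, index=fm.values.index, columns=fm.values.columns)
    )
    report.qc_rsd_after = qc_rsd(out).to_dict()
    return out, report


def pareto_scale(fm: FeatureMatrix) -> FeatureMatrix:
    """Mean-centre and divide by the square root of the standard
    deviation, with statistics computed on (and rows restricted to) the
    study samples; constant features map to all-zero columns.
    """
    if fm.is_scaled:
        raise ValidationError(
            "matrix is already pareto-scaled; scaling twice is not a no-op"
        )
    study = fm.study_values()
    mean = study.mean(axis=0)
    sd = study.std(axis=0, ddof=1)
    denom = np.sqrt(sd)
    z = (study - mean).div(denom.where(denom > 0, np.inf))
    return fm.replace_values(z, is_scaled=True)


def preprocess_pipeline(
    fm: FeatureMatrix,
    qc_missing_threshold: float = 0.5,
    span: float = 0.75,
    log_transform: bool = False,
) -> tuple[FeatureMatrix, FeatureMatrix, PreprocessReport]:
    """Run filter → impute → QC-RLSC → pareto.

    Returns ``(scaled, corrected, report)`` where ``corrected`` is the
    drift-corrected matrix on the abundance scale (QC rows retained) and
    ``scaled`` is the pareto-scaled study-sample matrix fed to every
    downstream model.
    """
    filtered, report = filter_by_qc_missing_rate(fm, qc_missing_threshold)
    imputed, rep2 = impute_min(filtered)
    if log_transform:
        logged = imputed.replace_values(np.log2(imputed.values))
    else:
        logged = imputed
    corrected, rep3 = qc_rlsc_correct(logged, span)
    scaled = pareto_scale(corrected)
    report.merge(rep2).merge(rep3)
    return scaled, corrected, report
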