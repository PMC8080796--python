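"""Core in-memory containers for the staging pipeline.

A :class:`FeatureMatrix` holds the injections × features abundance grid
(study samples interleaved with pooled-QC injections in run order), a
:class:`SampleMetadata` holds the per-patient stage label, covariates and
severity traits, and :class:`AnalysisConfig` collects every tunable
parameter of the analysis in one validated place.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

STAGES = ("SCAD", "UA", "MI")

#: covariates used for adjustment in every regression scan
ADJUSTMENT_COVARIATES = (
    "age",
    "sex",
    "hypertension",
    "diabetes",
    "smoking",
    "LDLC",
    "HDLC",
    "TG",
)

#: candidate pool for the traditional (risk-factor) diagnostic model
TRADITIONAL_CANDIDATES = ADJUSTMENT_COVARIATES + ("APOA", "Lp_a", "LVEF")

#: numeric severity traits used in module-trait grids and linear scans
SEVERITY_TRAITS = (
    "SYNTAX",
    "SYNTAX_II",
    "hs_CRP",
    "cTnI",
    "LVMI",
    "n_stenosed_vessels",
)


class FeatureMatrix:
    """Injections × features abundance grid with run annotations.

    Parameters
    ----------
    values
        DataFrame of non-negative abundances (NaN marks an explicit
        missing cell once zeros have been recoded after QC filtering).
        Rows are injections, columns are feature ids.
    injection_order
        Strictly increasing positive integers, one per injection.
    batch_id
        Analytical batch label per injection.
    is_qc
        True for pooled-QC injections.
    is_scaled
        Set by pareto scaling; guards against scaling twice.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        injection_order,
        batch_id,
        is_qc,
        *,
        is_scaled: bool = False,
        allow_missing: bool = False,
    ) -> None:
        values = pd.DataFrame(values).astype(float)
        n = len(values)
        order = np.asarray(injection_order, dtype=int)
        batch = np.asarray(batch_id)
        qc = np.asarray(is_qc, dtype=bool)
        if not (len(order) == len(batch) == len(qc) == n):
            raise ValidationError(
                "injection_order, batch_id and is_qc must each have one "
                f"entry per injection (got {len(order)}, {len(batch)}, "
                f"{len(qc)} for {n} injections)"
            )
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if n and (order <= 0).any():
            raise ValidationError("injection_order must be positive")
        if n and len(np.unique(order)) != n:
            raise ValidationError("injection_order must be unique")
        # keep rows in run order
        if n and not np.all(np.diff(order) > 0):
            sorter = np.argsort(order)
            values = values.iloc[sorter]
            order = order[sorter]
            batch = batch[sorter]
            qc = qc[sorter]
        arr = values.to_numpy()
        if not allow_missing and np.isnan(arr).any():
            raise ValidationError(
                "NaN abundance on input; encode missing cells as 0"
            )
        if not is_scaled and np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("abundances must be non-negative")
        self.values = values
        self.injection_order = order
        self.batch_id = batch
        self.is_qc = qc
        self.is_scaled = bool(is_scaled)

    # ------------------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index.astype(str))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns.astype(str))

    @property
    def n_injections(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def study_mask(self) -> np.ndarray:
        return ~self.is_qc

    def study_values(self) -> pd.DataFrame:
        """Abundances of the non-QC (study) injections only."""
        return self.values.loc[self.study_mask]

    def qc_values(self) -> pd.DataFrame:
        return self.values.loc[self.is_qc]

    def batches(self) -> list:
        """Batch labels in order of first appearance."""
        return list(pd.unique(self.batch_id))

    def replace_values(
        self, values: pd.DataFrame, *, is_scaled: bool | None = None,
        allow_missing: bool = False,
    ) -> "FeatureMatrix":
        """New matrix with the same run annotations but different values."""
        keep = np.isin(self.sample_ids, list(values.index.astype(str)))
        return FeatureMatrix(
            values,
            self.injection_order[keep],
            self.batch_id[keep],
            self.is_qc[keep],
            is_scaled=self.is_scaled if is_scaled is None else is_scaled,
            allow_missing=allow_missing,
        )

    def subset_features(self, feature_ids) -> "FeatureMatrix":
        fm = FeatureMatrix.__new__(FeatureMatrix)
        fm.values = self.values.loc[:, list(feature_ids)]
        fm.injection_order = self.injection_order
        fm.batch_id = self.batch_id
        fm.is_qc = self.is_qc
        fm.is_scaled = self.is_scaled
        return fm

    def copy(self) -> "FeatureMatrix":
        fm = FeatureMatrix.__new__(FeatureMatrix)
        fm.values = self.values.copy()
        fm.injection_order = self.injection_order.copy()
        fm.batch_id = self.batch_id.copy()
        fm.is_qc = self.is_qc.copy()
        fm.is_scaled = self.is_scaled
        return fm

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FeatureMatrix({self.n_injections} injections x "
            f"{self.n_features} features, {int(self.is_qc.sum())} QC, "
            f"{len(self.batches())} batch(es)"
            + (", pareto-scaled)" if self.is_scaled else ")")
        )


class SampleMetadata:
    """Per-study-sample stage label, covariates and severity traits."""

    def __init__(self, table: pd.DataFrame) -> None:
        table = pd.DataFrame(table)
        if "stage" not in table.columns:
            raise ValidationError("metadata must contain a 'stage' column")
        if table.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        bad = ~table["stage"].isin(STAGES) & table["stage"].notna()
        if bad.any():
            rows = table.index[bad].tolist()
            vals = table.loc[bad, "stage"].unique().tolist()
            raise ValidationError(
                f"unknown stage labels {vals} in rows {rows}; "
                f"allowed: {list(STAGES)}"
            )
        table = table.copy()
        table["stage"] = pd.Categorical(table["stage"], categories=STAGES)
        for col in table.columns:
            if col == "stage":
                continue
            coerced = pd.to_numeric(table[col], errors="coerce")
            newly_bad = coerced.isna() & table[col].notna()
            if newly_bad.any():
                raise ValidationError(
                    f"non-numeric values in covariate '{col}' at rows "
                    f"{table.index[newly_bad].tolist()}"
                )
            table[col] = coerced
        self.table = table

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index.astype(str))

    @property
    def stage(self) -> pd.Series:
        return self.table["stage"]

    def covariates(self, names=ADJUSTMENT_COVARIATES) -> pd.DataFrame:
        missing = [c for c in names if c not in self.table.columns]
        if missing:
            raise ConfigError(f"metadata lacks covariate column(s) {missing}")
        return self.table.loc[:, list(names)]

    def aligned_to(self, fm: FeatureMatrix) -> pd.DataFrame:
        """Metadata reindexed to the matrix's study injections.

        QC injections carry no metadata; study samples absent from the
        metadata appear as all-NaN rows.
        """
        study_ids = [
            s for s, q in zip(fm.sample_ids, fm.is_qc) if not q
        ]
        return self.table.reindex(study_ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        counts = self.stage.value_counts().to_dict()
        return f"SampleMetadata({len(self.table)} samples, stages={counts})"


@dataclass
class AnalysisConfig:
    """All tunable parameters of the staging analysis.

    Defaults follow widely used practice for pooled-QC metabolomics and
    weighted correlation networks; every value can be overridden from a
    YAML/JSON mapping.
    """

    qc_missing_threshold: float = 0.5
    loess_span: float = 0.75
    log_transform: bool = False
    soft_power: float = 4.0
    min_module_size: int = 5
    tree_cut_height: float = 0.99
    module_merge_cor: float = 0.9
    cv_folds: int = 5
    lasso_iterations: int = 200
    frequency_threshold: int = 100
    stepwise_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.qc_missing_threshold < 1:
            raise ConfigError("qc_missing_threshold must lie in (0, 1)")
        if not 0 < self.loess_span <= 1:
            raise ConfigError("loess_span must lie in (0, 1]")
        if self.soft_power <= 0:
            raise ConfigError("soft_power must be positive")
        if self.min_module_size < 2:
            raise ConfigError("min_module_size must be >= 2")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.lasso_iterations < 1:
            raise ConfigError("lasso_iterations must be >= 1")
        if self.frequency_threshold > self.lasso_iterations:
            raise ConfigError(
                "frequency_threshold cannot exceed lasso_iterations"
            )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)
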