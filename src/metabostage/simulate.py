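"""Synthetic cohort generator.

Emulates the statistical structure the staging analysis assumes: a
targeted-metabolomics run of ~900 patients in three ordered disease
stages (SCAD, UA, MI) with ~800 quantified features, pooled-QC
injections every ten study samples, smooth multiplicative
injection-order drift, block-correlated metabolite modules driven by
latent factors, stage-dependent mean shifts on a subset of features,
covariate confounding of stage membership, and missing-at-low-intensity
zeros.  A :class:`SyntheticTruth` record of everything planted is
returned alongside the data so recovery can be tested.

The generative model on the log scale, per feature ``j`` and study
sample ``i``::

    z_ij = r_j * f_{m(j), i} + delta_j(stage_i) + gamma_j(covariates_i)
           + sqrt(1 - r_j^2) * eps_ij
    abundance_ij = exp(base_j + s_j * z_ij) * drift_b(t_i) * tech_ij

where ``f`` are independent standard-normal module latent factors,
``r_j`` the within-module loading (pairwise within-module correlation
is ``r^2``), ``delta`` the planted stage shift in biological-SD units,
``drift_b`` a smooth positive per-batch function of injection order and
``tech`` multiplicative lognormal technical noise shared by study and
QC injections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .containers import AnalysisConfig, FeatureMatrix, SampleMetadata, STAGES
from .errors import ConfigError


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generator planted."""

    module_membership: dict  # feature id -> module label ("null" = none)
    stage_effects: dict  # feature id -> (delta UA-vs-SCAD, delta MI-vs-UA)
    module_trait_loadings: dict  # trait -> {module label: coefficient}
    drift: dict  # batch label -> drift factor per injection (run order)
    latent_factors: pd.DataFrame  # study samples x planted modules
    loading: float
    noise_cv: float
    seed: int

    def module_labels(self, feature_ids) -> np.ndarray:
        return np.asarray([self.module_membership[f] for f in feature_ids])

    def to_json_dict(self) -> dict:
        return {
            "module_membership": self.module_membership,
            "stage_effects": {
                k: list(map(float, v)) for k, v in self.stage_effects.items()
            },
            "module_trait_loadings": self.module_trait_loadings,
            "drift": {k: list(map(float, v)) for k, v in self.drift.items()},
            "loading": self.loading,
            "noise_cv": self.noise_cv,
            "seed": self.seed,
        }


def _smooth_drift(order: np.ndarray, amplitude: float, rng) -> np.ndarray:
    """exp(amplitude * cubic spline) through random knots; positive, smooth."""
    if amplitude == 0 or len(order) < 2:
        return np.ones(len(order))
    n_knots = 5
    knots = np.linspace(order.min(), order.max(), n_knots)
    vals = rng.normal(size=n_knots)
    vals /= max(np.abs(vals).max(), 1e-12)
    g = CubicSpline(knots, vals)(order)
    g /= max(np.abs(g).max(), 1e-12)
    return np.exp(amplitude * g)


def _stage_assignment(n_per_stage, z_age, sex, z_hdlc, rng) -> np.ndarray:
    """Exact stage counts with covariate-dependent membership odds.

    A multinomial logit on age, sex and HDLC gives each sample
    stage-membership weights; stages are then filled to their target
    sizes by weighted sampling without replacement, so adjustment for
    these covariates is non-trivial downstream.
    """
    n = len(z_age)
    # linear predictors vs SCAD baseline: UA slightly older, MI younger,
    # more male and lower HDLC (direction of the cohort's baseline table)
    eta_ua = 0.15 * z_age - 0.10 * z_hdlc
    eta_mi = -0.20 * z_age + 0.50 * sex - 0.60 * z_hdlc
    expo = np.exp(np.column_stack([np.zeros(n), eta_ua, eta_mi]))
    probs = expo / expo.sum(axis=1, keepdims=True)
    stage = np.empty(n, dtype=object)
    remaining = np.arange(n)
    for k in (2, 1, 0):  # fill MI first (strongest covariate signal)
        target = n_per_stage[k]
        if k == 0:
            chosen = remaining
        else:
            w = probs[remaining, k]
            w = w / w.sum()
            chosen = rng.choice(remaining, size=target, replace=False, p=w)
        stage[chosen] = STAGES[k]
        remaining = np.setdiff1d(remaining, chosen)
    return stage


def default_module_sizes(n_modules: int, n_features: int, rng) -> list[int]:
    """Sizes between 5 and 30, truncated to fit the feature count."""
    sizes = rng.integers(5, 31, size=n_modules)
    while sizes.sum() > n_features:
        sizes = sizes[:-1]
    return [int(s) for s in sizes]


def generate_cohort(
    n_per_stage=(310, 368, 264),
    n_features: int = 800,
    n_modules: int = 35,
    module_sizes=None,
    qc_interval: int = 10,
    config: AnalysisConfig | None = None,
    seed: int = 0,
    *,
    loading: float = 0.8,
    stage_effect: float = 0.35,
    n_stage_features: int = 15,
    drift_amplitude: float = 0.15,
    noise_cv: float = 0.08,
    n_batches: int = 1,
) -> tuple[FeatureMatrix, SampleMetadata, SyntheticTruth]:
    """Simulate a full staging cohort with planted structure.

    Parameters
    ----------
    n_per_stage
        Study samples per stage (SCAD, UA, MI).
    n_features, n_modules, module_sizes
        Feature-space layout; features beyond the planted modules are
        labelled ``"null"`` (uncorrelated, no stage effect).
    qc_interval
        One pooled-QC injection precedes every block of this many study
        samples.
    loading
        Latent-factor loading of module members (pairwise within-module
        correlation is ``loading**2``).
    stage_effect
        Mean shift per stage transition, in biological-SD units, planted
        on the first ``n_stage_features`` module features.
    drift_amplitude
        Log-scale amplitude of the smooth injection-order drift.
    noise_cv
        Technical (injection-to-injection) coefficient of variation,
        shared by study and QC injections.
    """
    rng = np.random.default_rng(seed)
    if config is None:
        config = AnalysisConfig(seed=seed)
    if qc_interval < 2:
        raise ConfigError("qc_interval must be >= 2")
    if module_sizes is None:
        module_sizes = default_module_sizes(n_modules, n_features, rng)
    module_sizes = list(map(int, module_sizes))
    if sum(module_sizes) > n_features:
        raise ConfigError(
            f"module sizes sum to {sum(module_sizes)} > n_features={n_features}"
        )
    n_modules = len(module_sizes)
    n_study = int(sum(n_per_stage))
    feature_ids = [f"F{j + 1:04d}" for j in range(n_features)]

    # ---- covariates ---------------------------------------------------
    age = rng.normal(63.0, 9.0, n_study)
    sex = (rng.random(n_study) < 0.80).astype(float)  # 1 = male
    hypertension = (rng.random(n_study) < 0.60).astype(float)
    diabetes = (rng.random(n_study) < 0.27).astype(float)
    smoking = (rng.random(n_study) < 0.30).astype(float)
    LDLC = np.maximum(rng.normal(2.5, 0.8, n_study), 0.3)
    HDLC = np.maximum(rng.normal(0.93, 0.20, n_study), 0.3)
    TG = np.exp(rng.normal(np.log(1.4), 0.4, n_study))
    APOA = np.maximum(rng.normal(1.02, 0.22, n_study), 0.2)
    Lp_a = np.exp(rng.normal(np.log(170.0), 0.8, n_study))
    LVEF = np.clip(rng.normal(62.0, 8.0, n_study), 15, 80)

    z_age = (age - age.mean()) / age.std()
    z_hdlc = (HDLC - HDLC.mean()) / HDLC.std()
    stage = _stage_assignment(tuple(n_per_stage), z_age, sex, z_hdlc, rng)
    stage_idx = np.array([STAGES.index(s) for s in stage])

    # ---- module structure --------------------------------------------
    membership = np.full(n_features, "null", dtype=object)
    pos = 0
    for m, size in enumerate(module_sizes):
        membership[pos : pos + size] = f"M{m + 1}"
        pos += size
    factors = rng.standard_normal((n_study, n_modules))
    r = np.where(membership != "null", loading, 0.0)

    # stage effects on the first planted-module features
    delta = np.zeros((n_features, 2))
    planted = np.flatnonzero(membership != "null")[:n_stage_features]
    signs = rng.choice([-1.0, 1.0], size=len(planted))
    delta[planted, 0] = stage_effect * signs
    delta[planted, 1] = stage_effect * signs

    # covariate loadings on a subset of features (confounding pressure)
    gamma_age = np.zeros(n_features)
    gamma_hdlc = np.zeros(n_features)
    conf = rng.random(n_features) < 0.3
    gamma_age[conf] = rng.normal(0.0, 0.2, conf.sum())
    gamma_hdlc[conf] = rng.normal(0.0, 0.2, conf.sum())

    module_col = np.zeros(n_features, dtype=int)  # factor index per feature
    for j, lab in enumerate(membership):
        module_col[j] = int(lab[1:]) - 1 if lab != "null" else 0

    f_part = factors[:, module_col] * r[None, :]
    cum_delta = np.zeros((n_study, n_features))
    cum_delta += (stage_idx >= 1)[:, None] * delta[:, 0][None, :]
    cum_delta += (stage_idx >= 2)[:, None] * delta[:, 1][None, :]
    gamma_part = np.outer(z_age, gamma_age) + np.outer(z_hdlc, gamma_hdlc)
    eps = rng.standard_normal((n_study, n_features))
    z = f_part + cum_delta + gamma_part + np.sqrt(1.0 - r**2)[None, :] * eps

    base = rng.uniform(np.log(1e4), np.log(1e6), n_features)
    s = rng.uniform(0.3, 0.7, n_features)  # biological log-SD per feature
    true_study = np.exp(base[None, :] + s[None, :] * z)
    qc_reference = true_study.mean(axis=0)  # pooled aliquot of all samples

    # ---- severity traits: linear in the latent factors ----------------
    k_tr = min(3, n_modules)
    trait_load: dict[str, dict[str, float]] = {}

    def _trait(name, intercept, scale, coefs, noise, extra=0.0, positive=False):
        lin = intercept + extra
        trait_load[name] = {}
        for m, c in enumerate(coefs[:k_tr]):
            lin = lin + scale * c * factors[:, m]
            trait_load[name][f"M{m + 1}"] = float(scale * c)
        vals = lin + noise * rng.standard_normal(n_study)
        return np.maximum(vals, 0.0) if positive else vals

    stage_sev = 0.8 * stage_idx  # severity rises along SCAD -> UA -> MI
    SYNTAX = _trait("SYNTAX", 15.0, 4.0, [1.0, 0.5, 0.0], 6.0,
                    extra=2.5 * stage_idx, positive=True)
    SYNTAX_II = _trait("SYNTAX_II", 27.0, 3.0, [0.8, 0.4, 0.0], 5.0,
                       positive=True)
    hs_CRP = np.exp(_trait("hs_CRP", 0.9, 0.5, [0.0, 1.0, 0.3], 0.7,
                           extra=0.5 * stage_sev))
    cTnI = np.exp(_trait("cTnI", -3.6, 0.5, [0.0, 0.4, 1.0], 0.9,
                         extra=1.6 * stage_sev))
    LVMI = _trait("LVMI", 115.0, 8.0, [0.5, 0.0, 0.6], 18.0, positive=True)
    nsv = np.clip(
        np.round(1.7 + 0.4 * factors[:, 0] + 0.25 * stage_idx
                 + 0.8 * rng.standard_normal(n_study)),
        0, 3,
    )
    trait_load["n_stenosed_vessels"] = {"M1": 0.4}

    # ---- run layout: shuffle study order, interleave QC ---------------
    perm = rng.permutation(n_study)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_study)]
    run_ids: list[str] = []
    run_rows: list[int] = []  # index into study arrays, -1 for QC
    qc_count = 0
    for b in range(0, n_study, qc_interval):
        qc_count += 1
        run_ids.append(f"QC{qc_count:03d}")
        run_rows.append(-1)
        for i in perm[b : b + qc_interval]:
            run_ids.append(sample_ids[i])
            run_rows.append(i)
    n_inj = len(run_ids)
    injection_order = np.arange(1, n_inj + 1)
    is_qc = np.array([r < 0 for r in run_rows])

    # batches split the run into contiguous, equal blocks
    batch_edges = np.linspace(0, n_inj, n_batches + 1).astype(int)
    batch_id = np.empty(n_inj, dtype=object)
    drift = np.ones(n_inj)
    drift_record: dict[str, np.ndarray] = {}
    for b in range(n_batches):
        lo, hi = batch_edges[b], batch_edges[b + 1]
        lab = f"B{b + 1}"
        batch_id[lo:hi] = lab
        d = _smooth_drift(injection_order[lo:hi].astype(float),
                          drift_amplitude, rng)
        drift[lo:hi] = d
        drift_record[lab] = d

    tech = np.exp(noise_cv * rng.standard_normal((n_inj, n_features)))
    values = np.empty((n_inj, n_features))
    for row, src in enumerate(run_rows):
        truth_row = qc_reference if src < 0 else true_study[src]
        values[row] = truth_row * drift[row] * tech[row]

    fm = FeatureMatrix(
        pd.DataFrame(values, index=run_ids, columns=feature_ids),
        injection_order,
        batch_id,
        is_qc,
    )

    meta = pd.DataFrame(
        {
            "stage": stage,
            "age": age,
            "sex": sex,
            "hypertension": hypertension,
            "diabetes": diabetes,
            "smoking": smoking,
            "LDLC": LDLC,
            "HDLC": HDLC,
            "TG": TG,
            "APOA": APOA,
            "Lp_a": Lp_a,
            "LVEF": LVEF,
            "SYNTAX": SYNTAX,
            "SYNTAX_II": SYNTAX_II,
            "hs_CRP": hs_CRP,
            "cTnI": cTnI,
            "LVMI": LVMI,
            "n_stenosed_vessels": nsv,
        },
        index=sample_ids,
    )
    md = SampleMetadata(meta)

    truth = SyntheticTruth(
        module_membership=dict(zip(feature_ids, membership)),
        stage_effects={
            f: (float(delta[j, 0]), float(delta[j, 1]))
            for j, f in enumerate(feature_ids)
        },
        module_trait_loadings=trait_load,
        drift=drift_record,
        latent_factors=pd.DataFrame(
            factors, index=sample_ids,
            columns=[f"M{m + 1}" for m in range(n_modules)],
        ),
        loading=loading,
        noise_cv=noise_cv,
        seed=seed,
    )
    return fm, md, truth


def inject_missingness(
    fm: FeatureMatrix,
    mnar_quantile: float,
    rate: float,
    seed: int = 0,
    bad_features=None,
    bad_qc_rate: float = 0.7,
) -> FeatureMatrix:
    """Zero out low-intensity cells (missing-at-low-intensity).

    Per feature, cells below its ``mnar_quantile`` abundance quantile are
    set to 0 with probability ``rate``.  Features listed in
    ``bad_features`` additionally lose QC cells at ``bad_qc_rate``
    (> 0.5 by default) so the QC missing-rate filter has positives.
    """
    if not 0 <= rate <= 1:
        raise ConfigError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    vals = fm.values.to_numpy().copy()
    thresh = np.quantile(vals, mnar_quantile, axis=0)
    low = vals <= thresh if mnar_quantile >= 1 else vals < thresh
    hit = low & (rng.random(vals.shape) < rate)
    vals[hit] = 0.0
    if bad_features:
        qc_rows = np.flatnonzero(fm.is_qc)
        cols = [fm.feature_ids.index(f) for f in bad_features]
        for c in cols:
            drop = qc_rows[rng.random(len(qc_rows)) < bad_qc_rate]
            vals[drop, c] = 0.0
    out = pd.DataFrame(vals, index=fm.values.index, columns=fm.values.columns)
    return fm.replace_values(out)


def planted_module_matrix(
    n_samples: int,
    module_sizes,
    loading: float,
    n_null: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian matrix with block-correlated planted modules.

    A lightweight front door to the latent-factor model for network
    benchmarks: member features share a standard-normal factor with the
    given loading, null features are independent noise.  Returns the
    samples × features frame and the true label per feature ("null" for
    the independent ones).
    """
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    for m, size in enumerate(module_sizes):
        f = rng.standard_normal(n_samples)
        block = loading * f[:, None] + np.sqrt(1 - loading**2) * (
            rng.standard_normal((n_samples, size))
        )
        cols.append(block)
        labels += [f"M{m + 1}"] * size
    if n_null:
        cols.append(rng.standard_normal((n_samples, n_null)))
        labels += ["null"] * n_null
    data = np.hstack(cols)
    ids = [f"F{j + 1:04d}" for j in range(data.shape[1])]
    return pd.DataFrame(data, columns=ids), np.asarray(labels)
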