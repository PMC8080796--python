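"""Model discrimination and reclassification metrics.

The C-statistic (ROC AUC — the proportion of concordant event /
non-event pairs, ties counted half) is reported with a DeLong
structural-components 95% confidence interval.  Two models are
compared by the continuous net reclassification improvement (NRI) and
the integrated discrimination improvement (IDI), with bootstrap
percentile intervals and normal-approximation p-values.  Group
separation of a diagnostic score is tested by Wilcoxon rank-sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm, rankdata

from .errors import ValidationError

Z975 = norm.ppf(0.975)


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValidationError("both classes must be present")
    return y


def roc_auc(scores, labels) -> tuple[float, tuple[float, float]]:
    """C-statistic with a DeLong 95% confidence interval.

    AUC = (concordant + 0.5 · tied) / (n_events · n_nonevents).  The
    variance combines the empirical variances of the per-event and
    per-nonevent placement values (structural components).
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    # placement of each event among non-events and vice versa
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    lo, hi = max(0.0, auc - Z975 * se), min(1.0, auc + Z975 * se)
    return auc, (lo, hi)


def _nri_point(p_old, p_new, y) -> float:
    up = p_new > p_old
    down = p_new < p_old
    ev, ne = y == 1, y == 0
    ev_term = up[ev].mean() - down[ev].mean()
    ne_term = down[ne].mean() - up[ne].mean()
    return float(ev_term + ne_term)


def _idi_point(p_old, p_new, y) -> float:
    ev, ne = y == 1, y == 0
    slope_new = p_new[ev].mean() - p_new[ne].mean()
    slope_old = p_old[ev].mean() - p_old[ne].mean()
    return float(slope_new - slope_old)


def _bootstrap_ci_p(stat_fn, p_old, p_new, y, n_boot, seed):
    """Percentile CI and normal-approximation p over resampled cohorts."""
    rng = np.random.default_rng(seed)
    n = len(y)
    est = stat_fn(p_old, p_new, y)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():  # degenerate resample: redraw
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() == yb.max():
                boots[b] = est
                continue
        boots[b] = stat_fn(p_old[idx], p_new[idx], yb)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    se = boots.std(ddof=1)
    p = 1.0 if se == 0 and est == 0 else float(2 * norm.sf(abs(est) / max(se, 1e-12)))
    return est, (float(lo), float(hi)), p


def continuous_nri(
    p_old, p_new, labels, n_boot: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float], float]:
    """Continuous (category-free) net reclassification improvement.

    Sum of the net proportions of events whose predicted probability
    rises and non-events whose probability falls under the new model;
    exact ties move neither way.  Ranges over [−2, 2].
    """
    y = _check_binary(labels)
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    if not (len(p_old) == len(p_new) == len(y)):
        raise ValidationError("p_old, p_new and labels must share a length")
    return _bootstrap_ci_p(_nri_point, p_old, p_new, y, n_boot, seed)


def idi(
    p_old, p_new, labels, n_boot: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float], float]:
    """Integrated discrimination improvement: difference in
    discrimination slope (mean event − mean non-event probability)."""
    y = _check_binary(labels)
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    if not (len(p_old) == len(p_new) == len(y)):
        raise ValidationError("p_old, p_new and labels must share a length")
    return _bootstrap_ci_p(_idi_point, p_old, p_new, y, n_boot, seed)


def compare_groups_wilcoxon(
    scores, groups, pairs=(("SCAD", "UA"), ("UA", "MI"))
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum p for each stated group pair."""
    scores = pd.Series(np.asarray(scores, dtype=float))
    groups = pd.Series(np.asarray(groups, dtype=object))
    rows = []
    for a, b in pairs:
        xa = scores[groups.to_numpy() == a].dropna()
        xb = scores[groups.to_numpy() == b].dropna()
        if len(xa) == 0 or len(xb) == 0:
            warnings.warn(f"empty group in pair ({a}, {b})")
            p = np.nan
        else:
            p = float(mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        rows.append({"group_a": a, "group_b": b, "p": p})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Paired-model comparison on one cohort and contrast."""

    comparison: str
    auc_old: float
    auc_old_ci: tuple
    auc_new: float
    auc_new_ci: tuple
    nri: float
    nri_ci: tuple
    nri_p: float
    idi: float
    idi_ci: tuple
    idi_p: float
    n_events: int
    n_nonevents: int

    def to_json_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "auc_old": self.auc_old,
            "auc_old_ci": list(self.auc_old_ci),
            "auc_new": self.auc_new,
            "auc_new_ci": list(self.auc_new_ci),
            "nri": self.nri,
            "nri_ci": list(self.nri_ci),
            "nri_p": self.nri_p,
            "idi": self.idi,
            "idi_ci": list(self.idi_ci),
            "idi_p": self.idi_p,
            "n_events": self.n_events,
            "n_nonevents": self.n_nonevents,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            comparison=d["comparison"],
            auc_old=float(d["auc_old"]),
            auc_old_ci=tuple(d["auc_old_ci"]),
            auc_new=float(d["auc_new"]),
            auc_new_ci=tuple(d["auc_new_ci"]),
            nri=float(d["nri"]),
            nri_ci=tuple(d["nri_ci"]),
            nri_p=float(d["nri_p"]),
            idi=float(d["idi"]),
            idi_ci=tuple(d["idi_ci"]),
            idi_p=float(d["idi_p"]),
            n_events=int(d["n_events"]),
            n_nonevents=int(d["n_nonevents"]),
        )


def evaluate_pair(
    p_old, p_new, labels, comparison: str = "",
    n_boot: int = 2000, seed: int = 0,
) -> EvaluationReport:
    """Full paired comparison: both C-statistics, continuous NRI, IDI."""
    y = _check_binary(labels)
    auc_o, ci_o = roc_auc(p_old, y)
    auc_n, ci_n = roc_auc(p_new, y)
    nri_est, nri_ci, nri_p = continuous_nri(p_old, p_new, y, n_boot, seed)
    idi_est, idi_ci, idi_p = idi(p_old, p_new, y, n_boot, seed + 1)
    return EvaluationReport(
        comparison=comparison,
        auc_old=auc_o, auc_old_ci=ci_o,
        auc_new=auc_n, auc_new_ci=ci_n,
        nri=nri_est, nri_ci=nri_ci, nri_p=nri_p,
        idi=idi_est, idi_ci=idi_ci, idi_p=idi_p,
        n_events=int((y == 1).sum()), n_nonevents=int((y == 0).sum()),
    )


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """FPR/TPR coordinates at every distinct score threshold."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    # keep the last point of each tied-score run
    distinct = np.r_[np.diff(s[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / ys.sum()]
    fpr = np.r_[0.0, fps[distinct] / (len(ys) - ys.sum())]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})
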