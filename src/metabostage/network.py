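"""Weighted correlation network analysis of metabolite abundances.

An unsigned weighted network is built from pairwise Pearson
correlations raised to a soft-thresholding power, turned into a
topological overlap matrix (TOM), and clustered (average linkage on TOM
dissimilarity) into modules of co-abundant metabolites.  Each module is
summarised by its eigenmetabolite — the first principal component of
its member features — which is then correlated (Spearman) against
clinical traits with Benjamini–Hochberg control of the false discovery
rate, compared across disease stages by rank-sum tests, and mined for
hub metabolites by intramodular connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

GREY = "grey"

#: readability aliases mapping deterministic size-ranked labels to the
#: colour names conventional in weighted correlation network software
MODULE_COLOR_ALIASES = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown",
    "steelblue", "paleturquoise", "violet", "darkolivegreen",
    "darkmagenta", "sienna",
)


def color_alias(label: str) -> str:
    """Conventional colour name for a size-ranked module label."""
    if label == GREY:
        return GREY
    idx = int(label[1:]) - 1
    return (
        MODULE_COLOR_ALIASES[idx]
        if idx < len(MODULE_COLOR_ALIASES)
        else label
    )


@dataclass
class ModuleAssignment:
    """Feature → module map plus per-module eigenmetabolite profiles."""

    labels: pd.Series  # feature id -> module label, "grey" = unassigned
    eigenmetabolites: pd.DataFrame  # samples × modules, unit-norm columns
    module_sizes: dict = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        return list(self.eigenmetabolites.columns)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.labels.index,
                "module": self.labels.to_numpy(),
                "color": [color_alias(m) for m in self.labels],
            }
        )


def _corr(data: pd.DataFrame) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = list(np.asarray(data.columns)[sd == 0])
        raise ValidationError(
            f"constant feature(s) {bad[:5]} have no defined correlation; "
            "remove them during preprocessing"
        )
    c = np.corrcoef(x, rowvar=False)
    return np.clip(c, -1.0, 1.0)


def adjacency_unsigned(data: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned weighted adjacency ``a_ij = |cor(i, j)| ** beta``."""
    if beta <= 0:
        raise ValidationError("soft-thresholding power must be positive")
    a = np.abs(_corr(data)) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=data.columns, columns=data.columns)


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R² of the log–log degree-distribution fit.

    Connectivities are binned into ``n_bins`` equal-width bins; a line
    is fitted to log10 p(k) vs log10 mean(k) over the occupied bins and
    R² is returned with the sign flipped when the slope is positive, so
    scale-free-like (decreasing) distributions score positively.
    """
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.array([
        k[idx == b].mean() if counts[b] else np.nan for b in range(n_bins)
    ])
    occupied = counts > 0
    p = counts[occupied] / counts.sum()
    km = means[occupied]
    if occupied.sum() < 3 or np.any(km <= 0):
        return 0.0
    lx, ly = np.log10(km), np.log10(p)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(
    data: pd.DataFrame, powers=tuple(range(1, 11))
) -> pd.DataFrame:
    """Scale-free fit index and connectivity for candidate powers."""
    if data.shape[1] < 20:
        raise ValidationError("soft-threshold scan needs >= 20 features")
    absc = np.abs(_corr(data))
    rows = []
    for beta in powers:
        a = absc**beta
        k = a.sum(axis=0) - 1.0  # off-diagonal row sums
        rows.append(
            {
                "power": beta,
                "fit_index": scale_free_fit_index(k),
                "mean_connectivity": float(k.mean()),
                "median_connectivity": float(np.median(k)),
            }
        )
    return pd.DataFrame(rows)


def tom_similarity(a: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency in [0, 1].

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`` with
    ``l_ij = Σ_u a_iu a_uj`` over shared neighbours and ``k`` the
    off-diagonal connectivity; ``TOM_ii = 1``.
    """
    av = np.asarray(a, dtype=float)
    if np.any(av < 0) or np.any(av > 1 + 1e-12):
        raise ValidationError("adjacency entries must lie in [0, 1]")
    if not np.allclose(av, av.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    a0 = av.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    shared = a0 @ a0  # includes u = i or j terms only via zeroed diagonal
    num = shared + a0
    den = np.minimum.outer(k, k) + 1.0 - a0
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=a.index, columns=a.columns)


def eigenmetabolites(
    data: pd.DataFrame, labels: pd.Series, modules=None
) -> pd.DataFrame:
    """First-PC summary profile per module, unit-norm, sign-oriented.

    Member features are standardised before the SVD; each column is
    flipped so its average correlation with the members is
    non-negative.  A singleton module's eigenmetabolite is its
    standardised feature.
    """
    if modules is None:
        modules = [m for m in pd.unique(labels) if m != GREY]
    out = {}
    for mod in modules:
        members = labels.index[labels == mod]
        sub = np.asarray(data.loc[:, members], dtype=float)
        sub = (sub - sub.mean(axis=0)) / np.where(
            sub.std(axis=0) > 0, sub.std(axis=0), 1.0
        )
        u, sv, _ = np.linalg.svd(sub, full_matrices=False)
        score = u[:, 0]
        with np.errstate(invalid="ignore"):
            cors = np.array([
                np.corrcoef(score, sub[:, j])[0, 1]
                for j in range(sub.shape[1])
            ])
        if np.nanmean(cors) < 0:
            score = -score
        out[mod] = score / np.linalg.norm(score)
    return pd.DataFrame(out, index=data.index)


def detect_modules(
    tom_dissim: pd.DataFrame,
    min_size: int = 5,
    data: pd.DataFrame | None = None,
    merge_cor: float = 0.9,
    cut_height: float = 0.99,
) -> ModuleAssignment:
    """Average-linkage clustering of TOM dissimilarity into modules.

    The dendrogram is cut at ``cut_height`` × its maximum merge height
    (the classic static cut; a reproducible stand-in for dynamic hybrid
    cutting); clusters below ``min_size`` fall into the grey
    (unassigned) module; modules whose eigenmetabolites correlate above
    ``merge_cor`` are merged.  Labels are assigned by decreasing module
    size: M1, M2, …
    """
    if min_size < 2:
        raise ValidationError("min_size must be >= 2")
    features = list(tom_dissim.index)
    n = len(features)
    if n < min_size:
        import warnings

        warnings.warn("fewer features than min_size; all features grey")
        labels = pd.Series(GREY, index=features)
        return ModuleAssignment(labels, pd.DataFrame(index=[]), {})
    d = np.asarray(tom_dissim, dtype=float)
    condensed = squareform((d + d.T) / 2.0, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    cut_h = float(cut_height * link[:, 2].max())
    raw = hierarchy.fcluster(link, t=cut_h, criterion="distance")
    labels = pd.Series(
        [f"C{c}" for c in raw], index=features, dtype=object
    )
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_size]
    labels[labels.isin(small)] = GREY

    if data is not None and (labels != GREY).any():
        labels = _merge_correlated(labels, data, merge_cor)

    # deterministic size-ranked relabel, ties broken by first feature id
    final_sizes = labels[labels != GREY].value_counts()
    order = sorted(
        final_sizes.index,
        key=lambda m: (-final_sizes[m], min(labels.index[labels == m])),
    )
    rename = {old: f"M{i + 1}" for i, old in enumerate(order)}
    labels = labels.map(lambda x: rename.get(x, GREY))
    eig = (
        eigenmetabolites(data, labels)
        if data is not None and rename
        else pd.DataFrame(index=(data.index if data is not None else []))
    )
    module_sizes = labels[labels != GREY].value_counts().to_dict()
    return ModuleAssignment(labels, eig, module_sizes)


def _merge_correlated(labels: pd.Series, data: pd.DataFrame, merge_cor: float):
    """Iteratively merge module pairs with eigenmetabolite cor > threshold."""
    labels = labels.copy()
    while True:
        mods = [m for m in pd.unique(labels) if m != GREY]
        if len(mods) < 2:
            return labels
        eig = eigenmetabolites(data, labels, mods)
        c = np.corrcoef(np.asarray(eig), rowvar=False)
        np.fill_diagonal(c, 0.0)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] <= merge_cor:
            return labels
        labels[labels == mods[j]] = mods[i]


def module_trait_correlation(
    eigen: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho/p per (module, trait) with grid-wide BH FDR.

    Uses pairwise-complete observations; cells with fewer than 3 paired
    values are NA and excluded from the FDR adjustment.
    """
    records = []
    for mod in eigen.columns:
        for trait in traits.columns:
            x = eigen[mod].to_numpy(dtype=float)
            y = pd.to_numeric(traits[trait], errors="coerce").to_numpy()
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.std(y[ok]) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = spearmanr(x[ok], y[ok])
            records.append(
                {"module": mod, "trait": trait, "rho": rho, "p": p}
            )
    grid = pd.DataFrame(records)
    ok = grid["p"].notna()
    grid["fdr"] = np.nan
    if ok.any():
        grid.loc[ok, "fdr"] = multipletests(
            grid.loc[ok, "p"], method="fdr_bh"
        )[1]
    return grid


def module_stage_comparison(
    eigen: pd.DataFrame, stage: pd.Series,
    contrasts=(("SCAD", "UA"), ("UA", "MI")),
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum p per module per stage contrast."""
    import warnings

    stage = stage.reindex(eigen.index)
    records = []
    for mod in eigen.columns:
        for a, b in contrasts:
            xa = eigen.loc[stage == a, mod].dropna()
            xb = eigen.loc[stage == b, mod].dropna()
            if len(xa) == 0 or len(xb) == 0:
                warnings.warn(f"empty stage group in contrast {a} vs {b}")
                p = np.nan
            else:
                p = float(
                    mannwhitneyu(xa, xb, alternative="two-sided").pvalue
                )
            records.append(
                {"module": mod, "contrast": f"{b}-vs-{a}", "p": p}
            )
    return pd.DataFrame(records)


def hub_metabolites(
    a: pd.DataFrame, assignment: ModuleAssignment, top_n: int = 5
) -> pd.DataFrame:
    """Rank features by intramodular connectivity kWithin per module."""
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    av = np.asarray(a, dtype=float)
    ids = list(a.index)
    labels = assignment.labels
    rows = []
    for mod in assignment.modules:
        members = [f for f in ids if labels.get(f) == mod]
        idx = [ids.index(f) for f in members]
        sub = av[np.ix_(idx, idx)]
        kwithin = sub.sum(axis=1) - np.diag(sub)
        ranked = sorted(
            zip(members, kwithin), key=lambda t: (-t[1], t[0])
        )
        for rank, (feat, kw) in enumerate(ranked[:top_n], start=1):
            rows.append(
                {
                    "module": mod,
                    "rank": rank,
                    "feature": feat,
                    "k_within": float(kw),
                }
            )
    return pd.DataFrame(rows)
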