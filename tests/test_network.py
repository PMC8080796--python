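"""Weighted network construction, module detection and module mining."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from metabostage import (
    ValidationError,
    adjacency_unsigned,
    detect_modules,
    eigenmetabolites,
    hub_metabolites,
    module_stage_comparison,
    module_trait_correlation,
    pick_soft_threshold,
    tom_similarity,
)
from metabostage.network import color_alias, scale_free_fit_index
from metabostage.simulate import planted_module_matrix


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Independent triple-loop TOM implementation (test oracle)."""
    a = np.asarray(a, dtype=float)
    p = a.shape[0]
    out = np.eye(p)
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            l_ij = sum(
                a[i, u] * a[u, j] for u in range(p) if u != i and u != j
            )
            k_i = sum(a[i, u] for u in range(p) if u != i)
            k_j = sum(a[j, u] for u in range(p) if u != j)
            out[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return out


def _random_adjacency(p, rng):
    c = rng.uniform(0, 1, (p, p))
    a = (c + c.T) / 2
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(
        a, index=[f"F{i}" for i in range(p)], columns=[f"F{i}" for i in range(p)]
    )


# ----------------------------------------------------------------------
# adjacency


def test_adjacency_worked_values():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(500)
    data = pd.DataFrame({"a": x, "b": x, "c": -x, "d": rng.standard_normal(500)})
    a = adjacency_unsigned(data, beta=4)
    assert a.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)
    assert a.loc["a", "c"] == pytest.approx(1.0, abs=1e-12)  # unsigned
    assert a.loc["a", "d"] < 0.01  # |r|^4 crushes weak correlation
    assert np.all(np.diag(a) == 1.0)


def test_adjacency_power_formula(rng):
    data = pd.DataFrame(rng.standard_normal((80, 6)))
    c = np.corrcoef(data.to_numpy(), rowvar=False)
    a = adjacency_unsigned(data, beta=4).to_numpy()
    off = ~np.eye(6, dtype=bool)
    np.testing.assert_allclose(a[off], np.abs(c[off]) ** 4, atol=1e-12)


def test_adjacency_rejects_constant_feature():
    data = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
    with pytest.raises(ValidationError, match="constant"):
        adjacency_unsigned(data, beta=4)
    with pytest.raises(ValidationError, match="positive"):
        adjacency_unsigned(pd.DataFrame(np.eye(3)), beta=0)


# ----------------------------------------------------------------------
# soft threshold


def test_soft_threshold_connectivity_decreases(rng):
    data, _ = planted_module_matrix(150, [10, 10], 0.8, n_null=10, seed=1)
    table = pick_soft_threshold(data)
    k = table["mean_connectivity"].to_numpy()
    assert np.all(np.diff(k) < 0)  # higher power, sparser network
    assert table.loc[table["power"] == 1, "mean_connectivity"].iloc[0] > 0


def test_soft_threshold_fit_improves_on_modular_data():
    data, _ = planted_module_matrix(200, [15, 12, 8], 0.8, n_null=15, seed=2)
    table = pick_soft_threshold(data).set_index("power")
    assert table.loc[4, "fit_index"] > table.loc[1, "fit_index"]


def test_soft_threshold_needs_enough_features(rng):
    with pytest.raises(ValidationError, match=">= 20"):
        pick_soft_threshold(pd.DataFrame(rng.standard_normal((30, 5))))


def test_scale_free_fit_index_signs():
    rng = np.random.default_rng(3)
    # heavy-tailed decreasing degree distribution scores positive
    k_sf = rng.pareto(2.0, 2000) + 0.5
    assert scale_free_fit_index(k_sf) > 0.5
    assert scale_free_fit_index(np.ones(10) * 2.0) == 0.0


# ----------------------------------------------------------------------
# TOM


def test_tom_worked_example():
    a = pd.DataFrame(
        [[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]],
        index=list("abc"), columns=list("abc"),
    )
    tom = tom_similarity(a)
    assert tom.loc["a", "b"] == pytest.approx(0.5, abs=1e-12)
    assert np.all(np.diag(tom) == 1.0)


def test_tom_identity_adjacency():
    a = pd.DataFrame(np.eye(4))
    tom = tom_similarity(a).to_numpy()
    off = ~np.eye(4, dtype=bool)
    assert np.all(tom[off] == 0.0)  # no edges, no overlap
    assert np.all(np.diag(tom) == 1.0)


def test_tom_matches_brute_force(rng):
    for _ in range(5):
        a = _random_adjacency(12, rng)
        tom = tom_similarity(a).to_numpy()
        np.testing.assert_allclose(
            tom, brute_force_tom(a.to_numpy()), atol=1e-12
        )


def test_tom_range_and_symmetry(rng):
    a = _random_adjacency(20, rng)
    tom = tom_similarity(a).to_numpy()
    assert np.all(tom >= 0) and np.all(tom <= 1 + 1e-12)
    np.testing.assert_allclose(tom, tom.T, atol=1e-12)


def test_tom_rejects_invalid_adjacency():
    with pytest.raises(ValidationError, match=r"\[0, 1\]"):
        tom_similarity(pd.DataFrame([[1.0, 1.5], [1.5, 1.0]]))
    with pytest.raises(ValidationError, match="symmetric"):
        tom_similarity(pd.DataFrame([[1.0, 0.2], [0.6, 1.0]]))


# ----------------------------------------------------------------------
# module detection


def _modules_from(data, min_size=5):
    a = adjacency_unsigned(data, beta=4)
    tom = tom_similarity(a)
    return detect_modules(1.0 - tom, min_size=min_size, data=data)


def test_detect_modules_two_planted_blocks():
    data, labels = planted_module_matrix(200, [15, 10], 0.8, seed=5)
    assignment = _modules_from(data)
    assert adjusted_rand_score(labels, assignment.labels.to_numpy()) == 1.0
    # labels are size-ranked
    assert assignment.module_sizes == {"M1": 15, "M2": 10}
    assert set(assignment.members("M1")) == set(data.columns[:15])


def test_detect_modules_null_features_go_grey():
    data, labels = planted_module_matrix(250, [12, 8], 0.85, n_null=6, seed=6)
    assignment = _modules_from(data)
    null_ids = data.columns[labels == "null"]
    assert (assignment.labels[null_ids] == "grey").mean() >= 0.5
    module_ids = data.columns[labels != "null"]
    assert (assignment.labels[module_ids] != "grey").all()


def test_detect_modules_small_clusters_grey(rng):
    # independent noise only: nothing should reach min_size coherently
    data = pd.DataFrame(
        rng.standard_normal((60, 4)), columns=[f"F{i}" for i in range(4)]
    )
    with pytest.warns(UserWarning, match="fewer features"):
        assignment = _modules_from(data, min_size=5)
    assert (assignment.labels == "grey").all()


def test_detect_modules_merges_duplicate_blocks():
    # two blocks driven by the same factor must merge into one module
    rng = np.random.default_rng(7)
    f = rng.standard_normal(300)
    block = lambda: 0.9 * f[:, None] + np.sqrt(1 - 0.81) * (
        rng.standard_normal((300, 8))
    )
    data = pd.DataFrame(
        np.hstack([block(), block()]),
        columns=[f"F{i:02d}" for i in range(16)],
    )
    assignment = _modules_from(data)
    # one module only: eigenmetabolite merging collapsed the two blocks
    assert assignment.modules == ["M1"]
    members = set(assignment.members("M1"))
    assert len(members & set(data.columns[:8])) >= 4
    assert len(members & set(data.columns[8:])) >= 4


def test_detect_modules_min_size_validation(rng):
    d = pd.DataFrame(np.eye(3))
    with pytest.raises(ValidationError, match="min_size"):
        detect_modules(d, min_size=1)


def test_color_alias_table():
    assert color_alias("M1") == "turquoise"
    assert color_alias("M2") == "blue"
    assert color_alias("grey") == "grey"
    assert color_alias("M99") == "M99"  # beyond the alias table


# ----------------------------------------------------------------------
# eigenmetabolites


def test_eigenmetabolite_recovers_latent_factor():
    data, labels = planted_module_matrix(400, [20], 0.9, seed=8)
    rng = np.random.default_rng(8)  # same stream the matrix used
    lab = pd.Series(labels, index=data.columns)
    eig = eigenmetabolites(data, lab)
    # eigenmetabolite correlates strongly with every member
    cors = [
        abs(np.corrcoef(eig["M1"], data[c])[0, 1]) for c in data.columns
    ]
    assert min(cors) > 0.7


def test_eigenmetabolite_sign_orientation():
    data, labels = planted_module_matrix(300, [10], 0.8, seed=9)
    lab = pd.Series(labels, index=data.columns)
    eig = eigenmetabolites(data, lab)
    cors = np.array(
        [np.corrcoef(eig["M1"], data[c])[0, 1] for c in data.columns]
    )
    assert cors.mean() > 0  # oriented towards the members
    # flipping every member flips the eigenmetabolite
    eig_flip = eigenmetabolites(-data, lab)
    np.testing.assert_allclose(
        eig_flip["M1"], -eig["M1"], atol=1e-10
    )


def test_eigenmetabolite_unit_norm_and_identical_members(rng):
    x = rng.standard_normal(50)
    data = pd.DataFrame({"a": x, "b": x, "c": x})
    lab = pd.Series(["M1"] * 3, index=data.columns)
    eig = eigenmetabolites(data, lab)
    assert np.linalg.norm(eig["M1"]) == pytest.approx(1.0, abs=1e-12)
    r = np.corrcoef(eig["M1"], x)[0, 1]
    assert r == pytest.approx(1.0, abs=1e-10)


# ----------------------------------------------------------------------
# module-trait correlation


def test_module_trait_perfect_monotone_association(rng):
    eig = pd.DataFrame({"M1": rng.standard_normal(60)})
    traits = pd.DataFrame({"t": np.exp(eig["M1"])})  # monotone transform
    grid = module_trait_correlation(eig, traits)
    assert grid["rho"].iloc[0] == pytest.approx(1.0, abs=1e-12)
    assert grid["p"].iloc[0] < 1e-10


def test_module_trait_spearman_rank_invariance(rng):
    eig = pd.DataFrame({"M1": rng.standard_normal(40)})
    t = rng.standard_normal(40) + 0.5 * eig["M1"].to_numpy()
    g1 = module_trait_correlation(eig, pd.DataFrame({"t": t}))
    g2 = module_trait_correlation(eig, pd.DataFrame({"t": np.exp(t)}))
    assert g1["rho"].iloc[0] == pytest.approx(g2["rho"].iloc[0], abs=1e-12)


def test_module_trait_handles_missing_and_constant(rng):
    eig = pd.DataFrame({"M1": rng.standard_normal(30)})
    traits = pd.DataFrame(
        {
            "mostly_nan": [1.0, 2.0] + [np.nan] * 28,
            "constant": np.ones(30),
            "ok": rng.standard_normal(30),
        },
        index=eig.index,
    )
    grid = module_trait_correlation(eig, traits).set_index("trait")
    assert np.isnan(grid.loc["mostly_nan", "rho"])
    assert np.isnan(grid.loc["constant", "rho"])
    assert np.isfinite(grid.loc["ok", "rho"])
    # FDR computed only over defined cells
    assert np.isnan(grid.loc["constant", "fdr"])
    assert np.isfinite(grid.loc["ok", "fdr"])


def test_module_trait_null_fdr_control(rng):
    # 5 modules x 8 independent traits: BH should rarely call anything
    eig = pd.DataFrame(
        rng.standard_normal((100, 5)), columns=[f"M{i+1}" for i in range(5)]
    )
    traits = pd.DataFrame(
        rng.standard_normal((100, 8)), columns=[f"t{i}" for i in range(8)]
    )
    grid = module_trait_correlation(eig, traits)
    assert (grid["fdr"] < 0.05).sum() == 0


# ----------------------------------------------------------------------
# module stage comparison


def test_module_stage_comparison_detects_shift(rng):
    n = 90
    stage = pd.Series(
        ["SCAD"] * 30 + ["UA"] * 30 + ["MI"] * 30,
        index=[f"S{i}" for i in range(n)],
    )
    shifted = np.r_[
        rng.standard_normal(30), rng.standard_normal(30),
        rng.standard_normal(30) + 2.0,
    ]
    eig = pd.DataFrame(
        {"M1": shifted, "M2": rng.standard_normal(n)}, index=stage.index
    )
    table = module_stage_comparison(eig, stage)
    t = table.set_index(["module", "contrast"])
    assert t.loc[("M1", "MI-vs-UA"), "p"] < 1e-6
    assert t.loc[("M1", "UA-vs-SCAD"), "p"] > 0.01
    assert t.loc[("M2", "MI-vs-UA"), "p"] > 0.001


def test_module_stage_comparison_empty_group_warns(rng):
    stage = pd.Series(["SCAD"] * 10, index=[f"S{i}" for i in range(10)])
    eig = pd.DataFrame({"M1": rng.standard_normal(10)}, index=stage.index)
    with pytest.warns(UserWarning, match="empty stage group"):
        table = module_stage_comparison(eig, stage)
    assert table["p"].isna().all()


# ----------------------------------------------------------------------
# hub metabolites


def test_hub_metabolites_match_brute_force(rng):
    data, labels = planted_module_matrix(120, [8, 6], 0.8, seed=10)
    a = adjacency_unsigned(data, beta=4)
    assignment = _modules_from(data)
    hubs = hub_metabolites(a, assignment, top_n=3)
    for mod in assignment.modules:
        members = assignment.members(mod)
        av = a.loc[members, members].to_numpy()
        kwithin = {
            f: av[i].sum() - av[i, i] for i, f in enumerate(members)
        }
        expected_top = max(kwithin, key=lambda f: (kwithin[f], ))
        got = hubs[(hubs["module"] == mod) & (hubs["rank"] == 1)]
        assert got["feature"].iloc[0] == expected_top
        assert got["k_within"].iloc[0] == pytest.approx(
            kwithin[expected_top], abs=1e-10
        )


def test_hub_metabolites_star_topology():
    # hub feature strongly tied to all members dominates kWithin
    rng = np.random.default_rng(11)
    hub = rng.standard_normal(300)
    spokes = 0.7 * hub[:, None] + np.sqrt(1 - 0.49) * rng.standard_normal(
        (300, 6)
    )
    data = pd.DataFrame(
        np.column_stack([hub, spokes]),
        columns=["hub"] + [f"s{i}" for i in range(6)],
    )
    assignment = _modules_from(data)
    a = adjacency_unsigned(data, beta=4)
    hubs = hub_metabolites(a, assignment, top_n=1)
    assert hubs["feature"].iloc[0] == "hub"


def test_hub_metabolites_validation(rng):
    data, _ = planted_module_matrix(80, [6], 0.8, seed=12)
    a = adjacency_unsigned(data, beta=4)
    assignment = _modules_from(data)
    with pytest.raises(ValidationError, match="top_n"):
        hub_metabolites(a, assignment, top_n=0)
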