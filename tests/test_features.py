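"""Target/pathway feature construction and design-matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from synerpath.features import (
    TYPE2_EXPRESSION,
    DrugTargetMap,
    PathwaySet,
    UnknownDrugError,
    assemble_design,
    pathway_features,
    target_features,
    type1_table,
    type2_table,
)


@pytest.fixture()
def small_world():
    genes = ["g1", "g2", "g3", "g4", "g5"]
    cells = ["c1", "c2"]
    active = pd.DataFrame(
        [[1, 0], [0, 1], [1, 1], [0, 0], [1, 0]], index=genes, columns=cells
    )
    essential = pd.DataFrame(
        [[0, 1], [1, 0], [0, 0], [1, 1], [0, 0]], index=genes, columns=cells
    )
    targets = DrugTargetMap({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
    return active, essential, targets


def test_target_features_set_arithmetic(small_world):
    active, essential, targets = small_world
    f = target_features("A", "B", "c1", active, essential, targets)
    assert f["n_D_union_ab"] == 3 and f["n_D_intersection_ab"] == 1
    # c1 active set {g1,g3,g5}; union {g1,g2,g3} -> overlap 2, ratio 2/3
    assert f["n_cell_c_expression"] == 3
    assert f["n_cell_c_expression_D_union_ab"] == 2
    assert f["ratio_expr_union"] == pytest.approx(2 / 3)
    # intersection {g2} not active in c1 -> 0
    assert f["n_cell_c_expression_D_intersection_ab"] == 0
    assert f["ratio_expr_intersection"] == 0.0
    # c1 essential set {g2,g4}: union overlap {g2} -> 1, ratio 1/2
    assert f["n_cell_c_essentiality_D_union_ab"] == 1
    assert f["ratio_ess_union"] == pytest.approx(1 / 2)


def test_unknown_drug_named_in_error(small_world):
    active, essential, targets = small_world
    with pytest.raises(UnknownDrugError, match="nosuch"):
        target_features("A", "nosuch", "c1", active, essential, targets)


def test_empty_target_set_rejected():
    with pytest.raises(ValueError, match="without targets"):
        DrugTargetMap({"A": set()})


def test_pathway_features_counts_and_bounds(small_world):
    active, essential, _ = small_world
    pw = PathwaySet("K1", "demo", frozenset({"g1", "g2", "g5"}))
    f = pathway_features(pw, "c1", active, essential)
    # active {g1,g3,g5}: overlap {g1,g5} -> 2 of total 3
    assert f["n_cell_c_expression_kegg_k"] == 2
    assert f["ratio_expr_kegg_k"] == pytest.approx(2 / 3)
    assert f["n_k"] == 3
    disjoint = PathwaySet("K2", "demo", frozenset({"g4"}))
    f2 = pathway_features(disjoint, "c1", active, essential)
    assert f2["n_cell_c_expression_kegg_k"] == 0
    assert f2["ratio_expr_kegg_k"] == 0.0
    everything = PathwaySet("K3", "demo", frozenset({"g1", "g3", "g5"}))
    f3 = pathway_features(everything, "c1", active, essential)
    assert f3["ratio_expr_kegg_k"] == pytest.approx(1.0)


def test_tables_match_scalar_features(small_world, rng):
    """Vectorized tables agree with the per-cell scalar computations."""
    active, essential, targets = small_world
    t1 = type1_table("A", "B", active, essential, targets)
    for cell in active.columns:
        scalar = target_features("A", "B", cell, active, essential, targets)
        for k, v in scalar.items():
            assert t1.loc[cell, k] == pytest.approx(v), (cell, k)
    pw = PathwaySet("K1", "demo", frozenset({"g1", "g2", "g5"}))
    t2 = type2_table(pw, active, essential)
    for cell in active.columns:
        scalar = pathway_features(pw, cell, active, essential)
        for k, v in scalar.items():
            assert t2.loc[cell, k] == pytest.approx(v), (cell, k)


def test_features_invariant_to_gene_order(small_world, rng):
    active, essential, targets = small_world
    perm = rng.permutation(len(active))
    f1 = target_features("A", "B", "c1", active, essential, targets)
    f2 = target_features("A", "B", "c1", active.iloc[perm],
                         essential.iloc[perm], targets)
    assert f1 == f2


def test_ratio_features_recompute_from_counts(rng):
    """Ratios always equal count / per-cell total on random fixtures."""
    genes = [f"g{i}" for i in range(40)]
    cells = [f"c{j}" for j in range(12)]
    active = pd.DataFrame(rng.integers(0, 2, size=(40, 12)), index=genes,
                          columns=cells)
    essential = pd.DataFrame(rng.integers(0, 2, size=(40, 12)), index=genes,
                             columns=cells)
    targets = DrugTargetMap({
        "A": set(rng.choice(genes, 4, replace=False)),
        "B": set(rng.choice(genes, 3, replace=False)),
    })
    t1 = type1_table("A", "B", active, essential, targets)
    for cell in cells:
        row = t1.loc[cell]
        for num, den, ratio in [
            ("n_cell_c_expression_D_union_ab", "n_cell_c_expression", "ratio_expr_union"),
            ("n_cell_c_expression_D_intersection_ab", "n_cell_c_expression", "ratio_expr_intersection"),
            ("n_cell_c_essentiality_D_union_ab", "n_cell_c_essentiality", "ratio_ess_union"),
            ("n_cell_c_essentiality_D_intersection_ab", "n_cell_c_essentiality", "ratio_ess_intersection"),
        ]:
            expect = row[num] / row[den] if row[den] > 0 else 0.0
            assert row[ratio] == pytest.approx(expect)
        assert row["n_cell_c_expression_D_intersection_ab"] <= row["n_cell_c_expression_D_union_ab"]


def _feature_frame(rng, n_cells=10):
    cells = [f"c{j}" for j in range(n_cells)]
    df = pd.DataFrame(index=pd.Index(cells, name="cell_line_id"))
    df["n_D_union_ab"] = 5.0
    df["n_D_intersection_ab"] = 1.0
    df["n_k"] = 30.0
    for col in ["n_cell_c_expression", "n_cell_c_expression_D_union_ab",
                "n_cell_c_expression_D_intersection_ab", "ratio_expr_union",
                "ratio_expr_intersection", "n_cell_c_essentiality",
                "n_cell_c_essentiality_D_union_ab",
                "n_cell_c_essentiality_D_intersection_ab", "ratio_ess_union",
                "ratio_ess_intersection", "n_cell_c_expression_kegg_k",
                "ratio_expr_kegg_k", "n_cell_c_essentiality_kegg_k",
                "ratio_ess_kegg_k"]:
        df[col] = rng.uniform(0, 10, size=n_cells)
    return df


def test_assemble_design_pa2_expression_columns(rng):
    df = _feature_frame(rng)
    resp = pd.Series([0, 1] * 5, index=df.index)
    d = assemble_design("p", "PA2", "expression", df, resp)
    assert list(d.X.columns) == TYPE2_EXPRESSION
    assert "n_k" in d.dropped_constant


def test_assemble_design_drops_constant_and_standardizes(rng):
    df = _feature_frame(rng, n_cells=30)
    resp = pd.Series([0, 1] * 15, index=df.index)
    d = assemble_design("p", "PA3", "combined", df, resp)
    assert set(d.dropped_constant) >= {"n_D_union_ab", "n_D_intersection_ab", "n_k"}
    np.testing.assert_allclose(d.X.mean(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(d.X.std(axis=0, ddof=0), 1, atol=1e-12)
    # PA3/combined keeps every varying type-1 and type-2 column
    assert d.X.shape[1] == 14


def test_assemble_design_drops_aliased_columns(rng):
    df = _feature_frame(rng)
    # make the intersection count an exact linear function of the union count
    df["n_cell_c_expression_D_intersection_ab"] = (
        2.0 * df["n_cell_c_expression_D_union_ab"] + 1.0
    )
    resp = pd.Series([0, 1] * 5, index=df.index)
    d = assemble_design("p", "PA1", "expression", df, resp)
    assert d.dropped_aliased == ["n_cell_c_expression_D_intersection_ab"]


def test_assemble_design_all_constant_is_degenerate():
    cells = [f"c{j}" for j in range(6)]
    df = pd.DataFrame(
        {c: 3.0 for c in ["n_cell_c_expression_kegg_k", "ratio_expr_kegg_k", "n_k"]},
        index=pd.Index(cells, name="cell_line_id"),
    )
    resp = pd.Series([0, 1, 0, 1, 0, 1], index=df.index)
    d = assemble_design("p", "PA2", "expression", df, resp)
    assert d.is_degenerate


def test_feature_row_matches_brute_force_sets(tiny):
    """Full feature rows recomputed from raw sets on the miniature study."""
    bundle, _ = tiny
    active = (bundle.presence == "P").astype(int)
    essential = (bundle.d2 < -0.5).astype(int)
    pair = bundle.pairs.iloc[0]
    train = list(essential.columns)
    t1 = type1_table(pair.drug_a, pair.drug_b, active, essential, bundle.targets,
                     cell_lines=train)
    ta = bundle.targets.targets[pair.drug_a]
    tb = bundle.targets.targets[pair.drug_b]
    for cell in train:
        act = {g for g in active.index if active.loc[g, cell]}
        ess = {g for g in essential.index if essential.loc[g, cell]}
        assert t1.loc[cell, "n_D_union_ab"] == len(ta | tb)
        assert t1.loc[cell, "n_cell_c_expression_D_union_ab"] == len((ta | tb) & act)
        assert t1.loc[cell, "n_cell_c_essentiality_D_intersection_ab"] == len(
            (ta & tb) & ess
        )
    pw = bundle.pathways[0]
    t2 = type2_table(pw, active, essential, cell_lines=train)
    for cell in train:
        act = {g for g in active.index if active.loc[g, cell]}
        assert t2.loc[cell, "n_cell_c_expression_kegg_k"] == len(pw.genes & act)
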