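"""Drug-target and pathway feature construction for per-pair models.

Two feature families are built per (drug pair, cell line), following the
standard count/ratio parameterization:

* type 1 (drug-target x cell line): sizes of the union and intersection
  of the two drugs' target-gene sets; per-cell totals of active and
  essential genes; counts of target genes that are active / essential in
  the cell line; and each count's ratio to the matching per-cell total.
* type 2 (pathway x cell line): counts of pathway genes active /
  essential in the cell line and their ratios to the per-cell totals,
  plus the pathway size.

Counts are computed over the post-filter gene universe by default, so the
denominators match the gene sets actually entering the scan.

``assemble_design`` turns a per-cell feature table into a standardized
regression design for one of three pathway analyses: PA1 uses type-1
features only, PA2 type-2 only, PA3 both; each restricted to the
expression-based columns, the essentiality-based columns, or both.
Columns constant across cell lines (always including the pair-level set
sizes and the pathway size) are dropped, as are columns linearly aliased
to earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UnknownDrugError",
    "DrugTargetMap",
    "PathwaySet",
    "DesignMatrix",
    "target_features",
    "pathway_features",
    "type1_table",
    "type2_table",
    "assemble_design",
    "TYPE1_EXPRESSION",
    "TYPE1_ESSENTIALITY",
    "TYPE2_EXPRESSION",
    "TYPE2_ESSENTIALITY",
    "PAIR_CONSTANT",
    "PATHWAY_CONSTANT",
]

# Column vocabulary of the two feature families.  The *_D_* columns count
# drug-target genes of the pair; the *_kegg_k columns count pathway genes.
PAIR_CONSTANT = ["n_D_union_ab", "n_D_intersection_ab"]
PATHWAY_CONSTANT = ["n_k"]
TYPE1_EXPRESSION = [
    "n_cell_c_expression",
    "n_cell_c_expression_D_union_ab",
    "n_cell_c_expression_D_intersection_ab",
    "ratio_expr_union",
    "ratio_expr_intersection",
]
TYPE1_ESSENTIALITY = [
    "n_cell_c_essentiality",
    "n_cell_c_essentiality_D_union_ab",
    "n_cell_c_essentiality_D_intersection_ab",
    "ratio_ess_union",
    "ratio_ess_intersection",
]
TYPE2_EXPRESSION = ["n_cell_c_expression_kegg_k", "ratio_expr_kegg_k"]
TYPE2_ESSENTIALITY = ["n_cell_c_essentiality_kegg_k", "ratio_ess_kegg_k"]

ANALYSES = ("PA1", "PA2", "PA3")
MODES = ("expression", "essentiality", "combined")


class UnknownDrugError(KeyError):
    """A drug identifier is missing from the drug-target map."""


@dataclass
class DrugTargetMap:
    """Mapping drug identifier -> set of target gene symbols.

    Drugs without any annotated target are rejected: they cannot
    contribute target features and are excluded from the analysis
    upstream.
    """

    targets: dict[str, set[str]]

    def __post_init__(self) -> None:
        empty = [d for d, t in self.targets.items() if not t]
        if empty:
            raise ValueError(f"drugs without targets are not allowed: {empty}")

    def targets_for(self, drug_id: str) -> set[str]:
        try:
            return self.targets[drug_id]
        except KeyError:
            raise UnknownDrugError(
                f"drug {drug_id!r} absent from the drug-target map"
            ) from None

    def pair_union(self, drug_a: str, drug_b: str) -> set[str]:
        return self.targets_for(drug_a) | self.targets_for(drug_b)

    def pair_intersection(self, drug_a: str, drug_b: str) -> set[str]:
        return self.targets_for(drug_a) & self.targets_for(drug_b)


@dataclass(frozen=True)
class PathwaySet:
    """A named gene set (e.g. one KEGG pathway)."""

    pathway_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id!r} has no genes")


@dataclass
class DesignMatrix:
    """Standardized per-pair regression design.

    ``X`` holds the retained, z-scored predictor columns (rows = training
    cell lines); ``y`` the binary synergy response aligned to the same
    cell lines.  ``dropped_constant`` and ``dropped_aliased`` record the
    columns removed during assembly.  A design with zero retained columns
    is degenerate and yields an NA p-value downstream.
    """

    pair_id: str
    analysis: str
    mode: str
    X: pd.DataFrame
    y: np.ndarray
    dropped_constant: list[str] = field(default_factory=list)
    dropped_aliased: list[str] = field(default_factory=list)

    @property
    def is_degenerate(self) -> bool:
        return self.X.shape[1] == 0


def _ratio(count: float, total: float) -> float:
    return count / total if total > 0 else 0.0


def target_features(
    drug_a: str,
    drug_b: str,
    cell_line: str,
    active: pd.DataFrame,
    essential: pd.DataFrame,
    targets: DrugTargetMap,
) -> dict[str, float]:
    """Type-1 feature values for one (drug pair, cell line).

    ``active`` and ``essential`` are binary gene x cell-line matrices
    restricted to the respective post-filter gene universes.
    """
    union = targets.pair_union(drug_a, drug_b)
    inter = targets.pair_intersection(drug_a, drug_b)

    act_genes = set(active.index[active[cell_line].astype(bool)])
    ess_genes = set(essential.index[essential[cell_line].astype(bool)])
    n_act, n_ess = len(act_genes), len(ess_genes)

    n_act_u = len(union & act_genes)
    n_act_i = len(inter & act_genes)
    n_ess_u = len(union & ess_genes)
    n_ess_i = len(inter & ess_genes)
    return {
        "n_D_union_ab": float(len(union)),
        "n_D_intersection_ab": float(len(inter)),
        "n_cell_c_expression": float(n_act),
        "n_cell_c_essentiality": float(n_ess),
        "n_cell_c_expression_D_union_ab": float(n_act_u),
        "n_cell_c_expression_D_intersection_ab": float(n_act_i),
        "ratio_expr_union": _ratio(n_act_u, n_act),
        "ratio_expr_intersection": _ratio(n_act_i, n_act),
        "n_cell_c_essentiality_D_union_ab": float(n_ess_u),
        "n_cell_c_essentiality_D_intersection_ab": float(n_ess_i),
        "ratio_ess_union": _ratio(n_ess_u, n_ess),
        "ratio_ess_intersection": _ratio(n_ess_i, n_ess),
    }


def pathway_features(
    pathway: PathwaySet,
    cell_line: str,
    active: pd.DataFrame,
    essential: pd.DataFrame,
) -> dict[str, float]:
    """Type-2 feature values for one (pathway, cell line)."""
    act_genes = set(active.index[active[cell_line].astype(bool)])
    ess_genes = set(essential.index[essential[cell_line].astype(bool)])
    n_act_k = len(pathway.genes & act_genes)
    n_ess_k = len(pathway.genes & ess_genes)
    return {
        "n_cell_c_expression_kegg_k": float(n_act_k),
        "ratio_expr_kegg_k": _ratio(n_act_k, len(act_genes)),
        "n_cell_c_essentiality_kegg_k": float(n_ess_k),
        "ratio_ess_kegg_k": _ratio(n_ess_k, len(ess_genes)),
        "n_k": float(len(pathway.genes)),
    }


def type1_table(
    drug_a: str,
    drug_b: str,
    active: pd.DataFrame,
    essential: pd.DataFrame,
    targets: DrugTargetMap,
    cell_lines: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Vectorized type-1 features for all cell lines of one drug pair."""
    cells = list(cell_lines) if cell_lines is not None else list(active.columns)
    union = targets.pair_union(drug_a, drug_b)
    inter = targets.pair_intersection(drug_a, drug_b)

    act = active[cells].astype(bool)
    ess = essential[cells].astype(bool)
    n_act = act.sum(axis=0).astype(float)
    n_ess = ess.sum(axis=0).astype(float)
    act_u = act.loc[act.index.isin(union)].sum(axis=0).astype(float)
    act_i = act.loc[act.index.isin(inter)].sum(axis=0).astype(float)
    ess_u = ess.loc[ess.index.isin(union)].sum(axis=0).astype(float)
    ess_i = ess.loc[ess.index.isin(inter)].sum(axis=0).astype(float)

    def ratio(c, t):
        return (c / t.replace(0, np.nan)).fillna(0.0)

    return pd.DataFrame(
        {
            "n_D_union_ab": float(len(union)),
            "n_D_intersection_ab": float(len(inter)),
            "n_cell_c_expression": n_act,
            "n_cell_c_essentiality": n_ess,
            "n_cell_c_expression_D_union_ab": act_u,
            "n_cell_c_expression_D_intersection_ab": act_i,
            "ratio_expr_union": ratio(act_u, n_act),
            "ratio_expr_intersection": ratio(act_i, n_act),
            "n_cell_c_essentiality_D_union_ab": ess_u,
            "n_cell_c_essentiality_D_intersection_ab": ess_i,
            "ratio_ess_union": ratio(ess_u, n_ess),
            "ratio_ess_intersection": ratio(ess_i, n_ess),
        },
        index=pd.Index(cells, name="cell_line_id"),
    )


def type2_table(
    pathway: PathwaySet,
    active: pd.DataFrame,
    essential: pd.DataFrame,
    cell_lines: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Vectorized type-2 features for all cell lines of one pathway."""
    cells = list(cell_lines) if cell_lines is not None else list(active.columns)
    act = active[cells].astype(bool)
    ess = essential[cells].astype(bool)
    n_act = act.sum(axis=0).astype(float)
    n_ess = ess.sum(axis=0).astype(float)
    act_k = act.loc[act.index.isin(pathway.genes)].sum(axis=0).astype(float)
    ess_k = ess.loc[ess.index.isin(pathway.genes)].sum(axis=0).astype(float)

    def ratio(c, t):
        return (c / t.replace(0, np.nan)).fillna(0.0)

    return pd.DataFrame(
        {
            "n_cell_c_expression_kegg_k": act_k,
            "ratio_expr_kegg_k": ratio(act_k, n_act),
            "n_cell_c_essentiality_kegg_k": ess_k,
            "ratio_ess_kegg_k": ratio(ess_k, n_ess),
            "n_k": float(len(pathway.genes)),
        },
        index=pd.Index(cells, name="cell_line_id"),
    )


def _columns_for(analysis: str, mode: str) -> list[str]:
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    cols: list[str] = []
    if analysis in ("PA1", "PA3"):
        cols += PAIR_CONSTANT
        if mode in ("expression", "combined"):
            cols += TYPE1_EXPRESSION
        if mode in ("essentiality", "combined"):
            cols += TYPE1_ESSENTIALITY
    if analysis in ("PA2", "PA3"):
        if mode in ("expression", "combined"):
            cols += TYPE2_EXPRESSION
        if mode in ("essentiality", "combined"):
            cols += TYPE2_ESSENTIALITY
        cols += PATHWAY_CONSTANT
    return cols


def assemble_design(
    pair_id: str,
    analysis: str,
    mode: str,
    features: pd.DataFrame,
    response: pd.Series,
) -> DesignMatrix:
    """Build a standardized design matrix for one per-pair model.

    ``features`` is a cell-line-indexed table containing (at least) the
    columns required by the requested analysis/mode; ``response`` is the
    binary synergy status indexed by the same cell lines.  Constant
    columns are dropped, remaining columns are z-scored, and columns
    linearly dependent on earlier columns (in the declared column order)
    are removed to make the design full rank.
    """
    cols = [c for c in _columns_for(analysis, mode) if c in features.columns]
    missing = set(_columns_for(analysis, mode)) - set(features.columns)
    if missing - set(PAIR_CONSTANT) - set(PATHWAY_CONSTANT):
        raise ValueError(f"feature table lacks required columns: {sorted(missing)}")
    cells = list(response.index)
    if list(features.index) == cells:
        sub = features[cols]
    else:
        sub = features.loc[cells, cols]
    M = sub.to_numpy(dtype=float)

    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=0)
    const_mask = sd == 0
    constant = [c for c, m in zip(cols, const_mask) if m]
    kept_names = [c for c, m in zip(cols, const_mask) if not m]
    Z = (M[:, ~const_mask] - mu[~const_mask]) / sd[~const_mask]

    # Greedy rank check in declared column order: a column is aliased if it
    # is (numerically) a linear combination of the intercept and the
    # columns already kept.  Incremental Gram-Schmidt against an
    # orthonormal basis keeps this O(n * k^2).
    n = len(cells)
    aliased: list[str] = []
    keep_cols: list[str] = []
    keep_vecs: list[np.ndarray] = []
    Q = [np.full(n, 1.0 / np.sqrt(n))]
    for j, col in enumerate(kept_names):
        v = Z[:, j]
        r = v.copy()
        for q in Q:
            r -= (q @ r) * q
        nrm = np.linalg.norm(r)
        if nrm < 1e-8 * max(1.0, np.linalg.norm(v)):
            aliased.append(col)
        else:
            Q.append(r / nrm)
            keep_cols.append(col)
            keep_vecs.append(v)
    X = pd.DataFrame(
        np.column_stack(keep_vecs) if keep_vecs else np.empty((n, 0)),
        index=pd.Index(cells, name="cell_line_id"), columns=keep_cols,
    )
    return DesignMatrix(
        pair_id=pair_id,
        analysis=analysis,
        mode=mode,
        X=X,
        y=response.loc[cells].to_numpy(dtype=float),
        dropped_constant=constant,
        dropped_aliased=aliased,
    )
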