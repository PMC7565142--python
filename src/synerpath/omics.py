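"""Expression activity calls, essentiality calls, and gene filtering.

Expression input is a gene x cell-line matrix of normalized microarray
intensities together with detection calls (P = present, M = marginal,
A = absent) already collapsed from probe to gene level.  A gene is called
*active* in a cell line when its detection call is present.

Essentiality input is a gene x cell-line matrix of RNAi dependency scores
normalized so that reference essential genes average about -1 and negative
controls about 0; a gene is called *essential* in a cell line when its
score falls strictly below a threshold (default -0.5).

Gene filtering removes expression genes active in too few cell lines or
with a low coefficient of variation, and essentiality genes never called
essential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "EssentialityMatrix",
    "GeneFilterReport",
    "call_active",
    "call_essential",
    "filter_genes",
    "ESSENTIALITY_THRESHOLD",
    "MIN_ACTIVE_FRACTION",
    "MIN_CV",
]

PRESENCE_CODES = frozenset({"P", "M", "A"})
ESSENTIALITY_THRESHOLD = -0.5
MIN_ACTIVE_FRACTION = 0.2
MIN_CV = 0.1


@dataclass
class ExpressionMatrix:
    """Normalized expression values plus detection calls, genes x cell lines."""

    values: pd.DataFrame
    presence: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.presence.index) or not (
            self.values.columns.equals(self.presence.columns)
        ):
            raise ValueError(
                "expression values and presence calls must share genes "
                "(rows) and cell lines (columns)"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene rows in expression matrix: {list(dups)[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        bad = set(np.unique(self.presence.to_numpy(dtype=object))) - PRESENCE_CODES
        if bad:
            raise ValueError(f"unknown presence call code(s): {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class EssentialityMatrix:
    """RNAi dependency (D2) scores, genes x cell lines."""

    d2: pd.DataFrame

    def __post_init__(self) -> None:
        if self.d2.index.has_duplicates:
            raise ValueError("duplicate gene rows in essentiality matrix")
        if not np.isfinite(self.d2.to_numpy(dtype=float)).all():
            raise ValueError("dependency scores must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.d2.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.d2.columns)


@dataclass
class GeneFilterReport:
    """Genes surviving the expression and essentiality filters."""

    retained_expression: list[str]
    retained_essentiality: list[str]
    excluded: dict[str, int] = field(default_factory=dict)


def call_active(expr: ExpressionMatrix, marginal_active: bool = False) -> pd.DataFrame:
    """Binary activity matrix from detection calls.

    A gene is active where its call is present; marginal calls count as
    inactive by default (``marginal_active=True`` flips that, for
    sensitivity analysis).
    """
    codes = {"P"} | ({"M"} if marginal_active else set())
    return expr.presence.isin(codes).astype(np.int8)


def call_essential(
    ess: EssentialityMatrix, threshold: float = ESSENTIALITY_THRESHOLD
) -> pd.DataFrame:
    """Binary essentiality matrix: 1 where the score is strictly below threshold.

    A score exactly at the threshold is nonessential.
    """
    return (ess.d2 < threshold).astype(np.int8)


def filter_genes(
    expr: ExpressionMatrix,
    active: pd.DataFrame,
    ess: EssentialityMatrix,
    essential: pd.DataFrame,
    min_active_fraction: float = MIN_ACTIVE_FRACTION,
    min_cv: float = MIN_CV,
    essential_rule: str = "any",
) -> GeneFilterReport:
    """Apply the gene filters and report retained genes and exclusion counts.

    Expression genes are retained when their active-cell count strictly
    exceeds ``min_active_fraction`` of the cell-line count and their
    coefficient of variation (sample SD / mean of the normalized values
    across cell lines) is at least ``min_cv``; genes with nonpositive mean
    have undefined CV and are excluded under the CV rule.

    Essentiality genes are retained under ``essential_rule="any"`` when
    essential in at least one cell line.  ``essential_rule="all"`` keeps
    only genes essential in every cell line (a far stricter reading,
    available for sensitivity analysis).
    """
    if essential_rule not in ("any", "all"):
        raise ValueError(f"unknown essential_rule {essential_rule!r}")
    n_cells = len(expr.cell_lines)
    counts = active.sum(axis=1)
    pass_presence = counts > min_active_fraction * n_cells

    means = expr.values.mean(axis=1)
    sds = expr.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sds / means
    pass_cv = (means > 0) & (cv >= min_cv)

    retained_expr = expr.values.index[pass_presence & pass_cv]

    ess_counts = essential.sum(axis=1)
    if essential_rule == "any":
        pass_ess = ess_counts >= 1
    else:
        pass_ess = ess_counts == len(ess.cell_lines)
    retained_ess = ess.d2.index[pass_ess]

    return GeneFilterReport(
        retained_expression=list(retained_expr),
        retained_essentiality=list(retained_ess),
        excluded={
            "low_presence": int((~pass_presence).sum()),
            "low_cv": int((pass_presence & ~pass_cv).sum()),
            "never_essential": int((~pass_ess).sum()),
        },
    )
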