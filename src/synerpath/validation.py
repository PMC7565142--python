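"""Wilcoxon rank-sum comparisons for hold-out validation.

The validation cohort carries expression data only, so a significant
pathway found in training is checked by a single-feature, distribution-
free comparison: the number of active pathway genes per cell line is
compared between cell lines with and without synergy for the drug pair,
using a two-sided Wilcoxon rank-sum (Mann-Whitney) test.  Small tie-free
samples use the exact null distribution; otherwise the normal
approximation with tie and continuity corrections is used, and the
chosen method is always reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["WilcoxonResult", "wilcoxon_rank_sum", "validate_pathway"]

EXACT_SIZE_LIMIT = 20


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided rank-sum comparison of two samples.

    ``statistic`` is the Mann-Whitney U of the first sample; ``method``
    is ``exact`` or ``normal_approx``; NA p-value when a group is empty.
    """

    statistic: float
    p_two_sided: float
    method: str
    n1: int
    n2: int


def wilcoxon_rank_sum(
    x: Iterable[float],
    y: Iterable[float],
    exact_limit: int = EXACT_SIZE_LIMIT,
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    Uses the exact permutation null when the pooled sample has no ties
    and at most ``exact_limit`` observations; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        return WilcoxonResult(np.nan, np.nan, "na", n1, n2)
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # all observations identical: no evidence either way
        return WilcoxonResult(n1 * n2 / 2.0, 1.0, "normal_approx", n1, n2)
    ties = np.unique(pooled).size < pooled.size
    if not ties and (n1 + n2) <= exact_limit:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        method = "normal_approx"
    return WilcoxonResult(
        float(res.statistic), float(min(res.pvalue, 1.0)), method, n1, n2
    )


def validate_pathway(
    pair_id: str,
    pathway_counts: pd.Series,
    synergy_status: pd.Series,
) -> WilcoxonResult:
    """Compare active-gene counts between synergy and no-synergy cells.

    ``pathway_counts`` holds the number of active pathway genes per cell
    line (the raw count, not the ratio); ``synergy_status`` the binary
    synergy call for the drug pair on the same cell lines.  An empty
    group (e.g. no synergistic validation cell line) yields an NA result
    with a warning.
    """
    cells = synergy_status.index.intersection(pathway_counts.index)
    s = synergy_status.loc[cells].astype(int)
    c = pathway_counts.loc[cells].astype(float)
    x = c[s == 1].to_numpy()
    y = c[s == 0].to_numpy()
    if x.size == 0 or y.size == 0:
        warnings.warn(
            f"pair {pair_id!r}: a synergy group is empty "
            f"(n_synergy={x.size}, n_no_synergy={y.size}); p-value is NA",
            stacklevel=2,
        )
        return WilcoxonResult(np.nan, np.nan, "na", x.size, y.size)
    return wilcoxon_rank_sum(x, y)
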