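"""Bliss-deviation scoring of drug-pair dose-response grids.

A combination screen measures cell growth under each drug alone across a
dose ladder and under every pairwise dose combination, all relative to an
untreated control and a time-zero anchor.  Growth fractions are expressed
in percent of control growth: 0 means complete stasis, 100 means growth
indistinguishable from control, and negative values mean net cell kill
below the starting population.

The synergy score implemented here is a modified Bliss-independence
deviation: for every dose pair the observed combination growth fraction is
compared against the expected growth under independent drug action (the
scaled product of the single-agent growth fractions, with single-agent
growth truncated at 100 and a min rule when either single agent already
kills), and the score is the mean of those observed-minus-expected
differences over the dose grid.  A combination is called synergistic in a
cell line when the score strictly exceeds a threshold (default 10), and a
drug pair enters downstream association analysis when it is synergistic
in at least a minimum number of cell lines (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DegenerateControlError",
    "GrowthFractionMatrix",
    "RawEndpointRecord",
    "SynergyRecord",
    "growth_fraction",
    "expected_combo_growth",
    "combo_score",
    "synergy_status",
    "score_growth_matrix",
    "select_combinations",
]

SYNERGY_THRESHOLD = 10.0
MIN_SYNERGISTIC_CELLS = 5


class DegenerateControlError(ValueError):
    """Control endpoint equals the time-zero measurement; growth undefined."""


@dataclass(frozen=True)
class RawEndpointRecord:
    """Raw assay endpoints for one well.

    Parameters
    ----------
    t0
        Time-zero measurement (assay units, e.g. optical density).
    t1
        Endpoint measurement after treatment.
    t10
        Endpoint measurement of the untreated control well.
    """

    t0: float
    t1: float
    t10: float


@dataclass
class GrowthFractionMatrix:
    """Growth fractions for one (drug pair, cell line) dose grid.

    ``y_a`` and ``y_b`` are single-agent growth fractions along the dose
    ladders of drug A (length p) and drug B (length q); ``y_ab`` is the
    p x q matrix of combination growth fractions.  Missing combination
    wells are represented as NaN and are excluded from the score mean.
    """

    pair_id: str
    cell_line_id: str
    y_a: np.ndarray
    y_b: np.ndarray
    y_ab: np.ndarray

    def __post_init__(self) -> None:
        self.y_a = np.atleast_1d(np.asarray(self.y_a, dtype=float))
        self.y_b = np.atleast_1d(np.asarray(self.y_b, dtype=float))
        self.y_ab = np.atleast_2d(np.asarray(self.y_ab, dtype=float))
        if self.y_a.ndim != 1 or self.y_b.ndim != 1:
            raise ValueError("y_a and y_b must be one-dimensional")
        if self.y_a.size < 1 or self.y_b.size < 1:
            raise ValueError("dose ladders must be non-empty")
        if self.y_ab.shape != (self.y_a.size, self.y_b.size):
            raise ValueError(
                f"y_ab shape {self.y_ab.shape} does not match dose grid "
                f"({self.y_a.size}, {self.y_b.size}) for pair "
                f"{self.pair_id!r} / cell line {self.cell_line_id!r}"
            )
        if not (np.isfinite(self.y_a).all() and np.isfinite(self.y_b).all()):
            raise ValueError("single-agent growth fractions must be finite")


@dataclass(frozen=True)
class SynergyRecord:
    """Bliss-deviation score and binary synergy status for one (pair, cell)."""

    pair_id: str
    cell_line_id: str
    combo_score: float
    status: int
    n_dose_pairs: int


def growth_fraction(rec: RawEndpointRecord) -> float:
    """Percent growth relative to control, anchored at time zero.

    Returns ``100 * (t1 - t0) / (t10 - t0)``.  Negative values indicate
    net cell kill; values above 100 indicate growth exceeding control.

    Raises
    ------
    DegenerateControlError
        If the control endpoint equals the time-zero measurement.
    """
    if rec.t10 == rec.t0:
        raise DegenerateControlError(
            f"control endpoint equals time zero (t0 = t10 = {rec.t0!r}); "
            "growth fraction undefined for this record"
        )
    return 100.0 * (rec.t1 - rec.t0) / (rec.t10 - rec.t0)


def expected_combo_growth(y_ap, y_bq):
    """Expected combination growth fraction under Bliss independence.

    If either single-agent growth fraction is nonpositive (the drug alone
    already holds or kills the population), the expectation is the smaller
    of the two.  Otherwise each single-agent growth fraction is truncated
    at 100 and the expectation is their product divided by 100.

    Accepts scalars or broadcastable arrays; returns a float for scalar
    input.
    """
    a = np.asarray(y_ap, dtype=float)
    b = np.asarray(y_bq, dtype=float)
    nonpos = (a <= 0) | (b <= 0)
    prod = np.minimum(a, 100.0) * np.minimum(b, 100.0) / 100.0
    out = np.where(nonpos, np.minimum(a, b), prod)
    if out.ndim == 0:
        return float(out)
    return out


def combo_score(g: GrowthFractionMatrix) -> float:
    """Mean observed-minus-expected growth difference over the dose grid.

    Positive scores indicate observed combination growth above the Bliss
    expectation under this sign convention; the downstream synergy call is
    ``score > threshold``.  Missing wells (NaN in ``y_ab``) are excluded
    and the averaging count reduced accordingly.

    For growth fractions confined to [0, 100] the score lies in
    [-100, 100]; no clamping is applied outside that domain.
    """
    z = expected_combo_growth(g.y_a[:, None], g.y_b[None, :])
    diffs = g.y_ab - z
    n = int(np.isfinite(diffs).sum())
    if n == 0:
        raise ValueError(
            f"no observed combination wells for pair {g.pair_id!r} / "
            f"cell line {g.cell_line_id!r}"
        )
    return float(np.nanmean(diffs))


def synergy_status(score: float, threshold: float = SYNERGY_THRESHOLD) -> int:
    """Binary synergy call: 1 iff the score strictly exceeds the threshold."""
    if not np.isfinite(score):
        raise ValueError(f"synergy status undefined for score {score!r}")
    return int(score > threshold)


def score_growth_matrix(
    g: GrowthFractionMatrix, threshold: float = SYNERGY_THRESHOLD
) -> SynergyRecord:
    """Score one dose grid and binarize it into a :class:`SynergyRecord`."""
    s = combo_score(g)
    return SynergyRecord(
        pair_id=g.pair_id,
        cell_line_id=g.cell_line_id,
        combo_score=s,
        status=synergy_status(s, threshold),
        n_dose_pairs=int(np.isfinite(g.y_ab).sum()),
    )


def select_combinations(
    records: Iterable[SynergyRecord],
    min_synergistic: int = MIN_SYNERGISTIC_CELLS,
) -> list[str]:
    """Drug pairs synergistic in at least ``min_synergistic`` cell lines.

    Returns pair identifiers sorted lexicographically.
    """
    counts: dict[str, int] = {}
    for rec in records:
        counts.setdefault(rec.pair_id, 0)
        counts[rec.pair_id] += int(rec.status)
    return sorted(pid for pid, c in counts.items() if c >= min_synergistic)
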