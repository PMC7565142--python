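"""Synthetic study generator with planted pathway-driven synergy.

Generates a complete, internally consistent synthetic study: expression
values with present/marginal/absent calls, RNAi dependency scores for
the training cohort, drug-target tables, pathway gene sets, and raw
dose-response endpoints for every (drug pair, cell line) — plus a
ground-truth sidecar that the analysis pipeline never reads.

The planted signal works through the pathway active-gene count (the
type-2 expression feature): for a causal drug pair, each cell line's
probability of true synergy follows a logistic model on the z-scored
active-gene count of the pair's causal pathway.  True synergy is then
written into the dose-response data as a positive Bliss deviation: each
combination well's growth fraction equals the Bliss expectation plus
``delta`` for synergistic cells, plus well noise, so that downstream
scoring recovers the labels and pathway analyses (not the target-only
analysis) carry signal.

Defaults mirror the real study's dimensions: 43 training and 16
validation cell lines, 3000 genes, 165 pathways, 69 drugs, 114 drug
pairs, 3x3 dose grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .features import DrugTargetMap, PathwaySet
from .scoring import expected_combo_growth

__all__ = ["SimulationConfig", "GroundTruth", "StudyData", "simulate", "make_fixture"]


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Structural sizes default to the real study's dimensions.  Noise and
    effect parameters: ``presence_beta`` are the Beta parameters of the
    per-gene prior probability of a present call; ``expr_log_mu`` /
    ``expr_log_sigma`` give the per-gene log-normal location prior
    (normal mean, sd) and log-sd range (uniform); ``d2_background`` and
    ``d2_essential`` are (mean, sd) of dependency scores in
    non-essential and essential cells; ``beta0``/``beta1`` are the
    intercept and per-SD slope of the synergy logit on the causal
    pathway's active-gene count; ``delta`` is the Bliss deviation (score
    units) written into synergistic combination wells; ``well_noise_sd``
    is the per-well growth-fraction noise sd (percent).
    """

    seed: int = 0
    n_train_cells: int = 43
    n_valid_cells: int = 16
    n_genes: int = 3000
    n_pathways: int = 165
    pathway_size_range: tuple[int, int] = (20, 200)
    n_drugs: int = 69
    targets_per_drug: tuple[int, int] = (1, 6)
    n_pairs: int = 114
    dose_grid: tuple[int, int] = (3, 3)
    presence_beta: tuple[float, float] = (2.0, 2.0)
    expr_log_mu: tuple[float, float] = (6.0, 1.0)
    expr_log_sigma: tuple[float, float] = (0.2, 0.6)
    d2_background: tuple[float, float] = (-0.1, 0.25)
    d2_essential: tuple[float, float] = (-0.8, 0.2)
    essential_fraction_beta: tuple[float, float] = (1.0, 6.0)
    marginal_prob: float = 0.05
    causal_fraction: float = 0.3
    beta0: float = -1.4
    beta1: float = 1.1
    delta: float = 30.0
    well_noise_sd: float = 5.0
    t0_value: float = 100.0
    control_value: float = 400.0

    def validate(self) -> None:
        if min(self.n_train_cells, self.n_genes, self.n_pathways,
               self.n_drugs, self.n_pairs) < 1 or self.n_valid_cells < 0:
            raise ConfigError("all structural counts must be positive")
        if self.pathway_size_range[1] > self.n_genes:
            raise ConfigError(
                f"pathway size up to {self.pathway_size_range[1]} exceeds "
                f"n_genes = {self.n_genes}"
            )
        if self.targets_per_drug[1] > self.n_genes:
            raise ConfigError("targets per drug exceed the gene universe")
        if self.n_pairs > self.n_drugs * (self.n_drugs - 1) // 2:
            raise ConfigError("more pairs requested than distinct drug pairs exist")
        if not (0.0 <= self.causal_fraction <= 1.0):
            raise ConfigError("causal_fraction must lie in [0, 1]")
        if not (0.0 <= self.marginal_prob <= 1.0):
            raise ConfigError("marginal_prob must lie in [0, 1]")
        if self.control_value == self.t0_value:
            raise ConfigError("control endpoint must differ from time zero")


@dataclass
class GroundTruth:
    """What was planted: never consumed by the analysis pipeline."""

    pairs: pd.DataFrame      # pair_id, drug_a, drug_b, causal_pathway
    labels: pd.DataFrame     # pair_id, cell_line_id, s_true, p_true, delta
    genes: pd.DataFrame      # gene, prevalence, n_essential_cells
    well_excursion_fraction: float = 0.0  # wells outside [0, 100] growth


@dataclass
class StudyData:
    """In-memory bundle of every input the pipeline consumes."""

    expression: pd.DataFrame          # genes x all cells
    presence: pd.DataFrame            # genes x all cells, {P, M, A}
    d2: pd.DataFrame                  # genes x training cells
    targets: DrugTargetMap
    pathways: list[PathwaySet]
    dose_response: pd.DataFrame       # long CSV schema
    cohorts: pd.Series                # cell -> {train, validation}
    pairs: pd.DataFrame               # pair_id, drug_a, drug_b

    @property
    def train_cells(self) -> list[str]:
        return list(self.cohorts.index[self.cohorts == "train"])

    @property
    def valid_cells(self) -> list[str]:
        return list(self.cohorts.index[self.cohorts == "validation"])


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _mono_curve(dose_idx: np.ndarray, k: float, d50: float) -> np.ndarray:
    """Decreasing three-parameter logistic dose-response in [0, 100]."""
    return 100.0 / (1.0 + np.exp(k * (dose_idx - d50)))


def simulate(config: SimulationConfig, out_dir: str | Path | None = None
             ) -> tuple[StudyData, GroundTruth]:
    """Generate the full synthetic study; deterministic given the seed.

    Writes the standard input files plus ground-truth TSVs when
    ``out_dir`` is given.  Returns the in-memory bundle and truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_cells = config.n_train_cells + config.n_valid_cells
    cells = [f"CL{i + 1:03d}" for i in range(n_cells)]
    train = cells[: config.n_train_cells]
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    drugs = [f"D{i + 1:03d}" for i in range(config.n_drugs)]

    # --- expression + presence -------------------------------------------
    prevalence = rng.beta(*config.presence_beta, size=config.n_genes)
    u = rng.random((config.n_genes, n_cells))
    present = u < prevalence[:, None]
    marginal = (~present) & (rng.random((config.n_genes, n_cells))
                             < config.marginal_prob)
    presence = np.where(present, "P", np.where(marginal, "M", "A"))

    mu_g = rng.normal(*config.expr_log_mu, size=config.n_genes)
    sig_g = rng.uniform(*config.expr_log_sigma, size=config.n_genes)
    expr = np.exp(mu_g[:, None] + sig_g[:, None]
                  * rng.standard_normal((config.n_genes, n_cells)))

    expression = pd.DataFrame(expr, index=genes, columns=cells)
    presence_df = pd.DataFrame(presence, index=genes, columns=cells)

    # --- dependency scores (training cohort only) ------------------------
    ess_frac = rng.beta(*config.essential_fraction_beta, size=config.n_genes)
    ess_mask = rng.random((config.n_genes, config.n_train_cells)) < ess_frac[:, None]
    d2 = np.where(
        ess_mask,
        rng.normal(*config.d2_essential, size=ess_mask.shape),
        rng.normal(*config.d2_background, size=ess_mask.shape),
    )
    d2_df = pd.DataFrame(d2, index=genes, columns=train)

    # --- drugs, targets, pathways ----------------------------------------
    tmin, tmax = config.targets_per_drug
    target_map: dict[str, set[str]] = {}
    for d in drugs:
        k = int(rng.integers(tmin, tmax + 1))
        target_map[d] = set(rng.choice(genes, size=k, replace=False))
    all_targets = sorted(set().union(*target_map.values()))

    smin, smax = config.pathway_size_range
    pathways: list[PathwaySet] = []
    for i in range(config.n_pathways):
        size = int(rng.integers(smin, smax + 1))
        members = set(rng.choice(genes, size=size, replace=False))
        pathways.append(
            PathwaySet(f"PWY{i + 1:03d}", f"synthetic pathway {i + 1}",
                       frozenset(members))
        )
    # guarantee at least one pathway carries a drug-target gene so the
    # target-pathway restriction downstream never empties the analysis
    if not any(pw.genes & set(all_targets) for pw in pathways):
        pathways[0] = PathwaySet(
            pathways[0].pathway_id, pathways[0].name,
            frozenset(pathways[0].genes | {all_targets[0]}),
        )

    # --- drug pairs and causal assignment --------------------------------
    pair_idx = set()
    while len(pair_idx) < config.n_pairs:
        i, j = rng.integers(0, config.n_drugs, size=2)
        if i != j:
            pair_idx.add((min(i, j), max(i, j)))
    pair_list = sorted(pair_idx)
    pair_ids = [f"{drugs[i]}_{drugs[j]}" for i, j in pair_list]

    n_causal = int(round(config.causal_fraction * config.n_pairs))
    causal_pairs = list(rng.choice(config.n_pairs, size=n_causal, replace=False))
    target_pathways = [pw for pw in pathways if pw.genes & set(all_targets)]
    causal_pool = target_pathways if target_pathways else pathways

    active = (presence_df == "P").astype(int)

    pair_rows, label_rows = [], []
    s_true = np.zeros((config.n_pairs, n_cells), dtype=int)
    for pi, (i, j) in enumerate(pair_list):
        causal_id = ""
        if pi in causal_pairs:
            pw = causal_pool[int(rng.integers(0, len(causal_pool)))]
            causal_id = pw.pathway_id
            counts = active.loc[active.index.isin(pw.genes)].sum(axis=0).astype(float)
            mu, sd = counts[train].mean(), counts[train].std(ddof=0)
            z = (counts - mu) / sd if sd > 0 else counts * 0.0
            p_syn = _logistic(config.beta0 + config.beta1 * z.to_numpy())
        else:
            p_syn = np.full(n_cells, _logistic(config.beta0))
        s = (rng.random(n_cells) < p_syn).astype(int)
        s_true[pi] = s
        pair_rows.append({"pair_id": pair_ids[pi], "drug_a": drugs[i],
                          "drug_b": drugs[j], "causal_pathway": causal_id})
        for ci, cell in enumerate(cells):
            label_rows.append({"pair_id": pair_ids[pi], "cell_line_id": cell,
                               "s_true": int(s[ci]), "p_true": float(p_syn[ci]),
                               "delta": config.delta * s[ci]})

    pairs_df = pd.DataFrame(pair_rows)

    # --- dose-response endpoints -----------------------------------------
    p_doses, q_doses = config.dose_grid
    # monotone decreasing curves, one parameter draw per (drug, cell)
    kk = rng.uniform(0.8, 2.0, size=(config.n_drugs, n_cells))
    d50 = rng.uniform(1.0, 3.0, size=(config.n_drugs, n_cells))

    span = config.control_value - config.t0_value
    rows = []
    n_out = 0
    n_wells = 0

    def well(pair_id, cell, da, db, ia, ib, role, y):
        value = config.t0_value + y / 100.0 * span
        rows.append((pair_id, cell, da, db, ia, ib, role, value))

    for pi, (i, j) in enumerate(pair_list):
        pid = pair_ids[pi]
        da, db = drugs[i], drugs[j]
        for ci, cell in enumerate(cells):
            ya = _mono_curve(np.arange(1, p_doses + 1), kk[i, ci], d50[i, ci])
            yb = _mono_curve(np.arange(1, q_doses + 1), kk[j, ci], d50[j, ci])
            z = expected_combo_growth(ya[:, None], yb[None, :])
            yab = (z + config.delta * s_true[pi, ci]
                   + rng.normal(0.0, config.well_noise_sd, size=z.shape))
            ya_obs = ya + rng.normal(0.0, config.well_noise_sd, size=ya.shape)
            yb_obs = yb + rng.normal(0.0, config.well_noise_sd, size=yb.shape)
            n_wells += yab.size + ya_obs.size + yb_obs.size
            n_out += int(((yab < 0) | (yab > 100)).sum())
            n_out += int(((ya_obs < 0) | (ya_obs > 100)).sum())
            n_out += int(((yb_obs < 0) | (yb_obs > 100)).sum())

            rows.append((pid, cell, da, db, 0, 0, "t0", config.t0_value))
            rows.append((pid, cell, da, db, 0, 0, "control", config.control_value))
            for p in range(p_doses):
                well(pid, cell, da, db, p + 1, 0, "mono_a", ya_obs[p])
            for q in range(q_doses):
                well(pid, cell, da, db, 0, q + 1, "mono_b", yb_obs[q])
            for p in range(p_doses):
                for q in range(q_doses):
                    well(pid, cell, da, db, p + 1, q + 1, "combo", yab[p, q])

    dose_df = pd.DataFrame(
        rows,
        columns=["pair_id", "cell_line_id", "drug_a", "drug_b",
                 "dose_index_a", "dose_index_b", "role", "value"],
    )

    cohorts = pd.Series(
        ["train"] * config.n_train_cells + ["validation"] * config.n_valid_cells,
        index=pd.Index(cells, name="cell_line_id"), name="cohort",
    )

    bundle = StudyData(
        expression=expression, presence=presence_df, d2=d2_df,
        targets=DrugTargetMap(target_map), pathways=pathways,
        dose_response=dose_df, cohorts=cohorts,
        pairs=pairs_df[["pair_id", "drug_a", "drug_b"]],
    )
    truth = GroundTruth(
        pairs=pairs_df,
        labels=pd.DataFrame(label_rows),
        genes=pd.DataFrame({
            "gene": genes,
            "prevalence": prevalence,
            "n_essential_cells": ess_mask.sum(axis=1),
        }),
        well_excursion_fraction=n_out / n_wells if n_wells else 0.0,
    )

    if out_dir is not None:
        from .io import write_bundle, write_truth

        out_dir = Path(out_dir)
        write_bundle(bundle, out_dir)
        write_truth(truth, out_dir)
    return bundle, truth


_FIXTURES: dict[str, SimulationConfig] = {
    # hand-checkable miniature
    "tiny": SimulationConfig(
        n_train_cells=4, n_valid_cells=2, n_genes=30, n_pathways=4,
        pathway_size_range=(5, 10), n_drugs=5, targets_per_drug=(1, 3),
        n_pairs=3, causal_fraction=1 / 3,
    ),
    # no planted feature effect: labels independent of all features
    "null": SimulationConfig(
        n_genes=400, n_pathways=40, pathway_size_range=(10, 30),
        n_drugs=20, n_pairs=30, causal_fraction=0.0, beta1=0.0,
    ),
    # large effect: odds ratio e^1.2 > 3 per SD, strong Bliss deviation
    "strong_signal": SimulationConfig(
        n_genes=300, n_pathways=12, pathway_size_range=(10, 40),
        n_drugs=16, n_pairs=12, causal_fraction=0.5, beta0=-1.2,
        beta1=1.2, delta=40.0,
    ),
}


def make_fixture(name: str, seed: int = 0, out_dir: str | Path | None = None
                 ) -> tuple[StudyData, GroundTruth]:
    """Generate one of the named study fixtures (tiny / null / strong_signal)."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    return simulate(replace(_FIXTURES[name], seed=seed), out_dir=out_dir)


def fixture_config(name: str, seed: int = 0) -> SimulationConfig:
    """The configuration behind a named fixture."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    return replace(_FIXTURES[name], seed=seed)
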