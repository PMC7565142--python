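"""Model/Results facade tying the pipeline stages together.

``SynergyAssociationModel`` holds a study bundle (dose-response screens,
expression calls, dependency scores, drug targets, pathway gene sets)
plus analysis settings; ``fit()`` runs scoring, pair selection, gene
filtering, feature construction and the logistic association scans, and
returns a ``SynergyAssociationResults`` carrying the per-model
p-values, the minimum-p aggregations, and methods for FDR tables,
overlap/correlation summaries, target-group comparisons, hold-out
validation and a text summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import omics
from .features import DrugTargetMap, PathwaySet
from .io import (
    DataError,
    PipelineConfig,
    dose_response_to_matrices,
    make_manifest,
    read_inputs,
    write_synergy,
)
from .omics import EssentialityMatrix, ExpressionMatrix
from .scoring import score_growth_matrix, select_combinations
from .simulate import StudyData
from .validation import validate_pathway

__all__ = ["SynergyAssociationModel", "SynergyAssociationResults", "run_pipeline"]


class SynergyAssociationModel:
    """Per-pair logistic association scans over a drug-combination study.

    Parameters
    ----------
    data
        The in-memory study bundle (see :class:`synerpath.simulate.StudyData`).
    config
        Thresholds and analysis selections; defaults reproduce the
        study's constants.
    """

    def __init__(self, data: StudyData, config: PipelineConfig | None = None):
        self.data = data
        self.config = config or PipelineConfig()
        self.config.validate()

    @classmethod
    def from_files(cls, config: PipelineConfig, base_dir: str | Path = "."
                   ) -> "SynergyAssociationModel":
        return cls(read_inputs(config, base_dir), config)

    # -- stage helpers ----------------------------------------------------

    def score(self) -> list:
        """Bliss-deviation scores and synergy calls for every (pair, cell)."""
        mats = dose_response_to_matrices(self.data.dose_response)
        return [
            score_growth_matrix(g, self.config.synergy_threshold)
            for g in mats.values()
        ]

    def fit(self) -> "SynergyAssociationResults":
        cfg = self.config
        data = self.data
        train = data.train_cells

        records = self.score()
        synergy = pd.DataFrame([r.__dict__ for r in records])
        train_records = [r for r in records if r.cell_line_id in train]
        selected = select_combinations(train_records, cfg.min_synergistic)

        expr = ExpressionMatrix(
            values=data.expression[train], presence=data.presence[train]
        )
        active_all = omics.call_active(
            ExpressionMatrix(values=data.expression, presence=data.presence),
            marginal_active=cfg.marginal_active,
        )
        ess = EssentialityMatrix(d2=data.d2)
        essential = omics.call_essential(ess, cfg.essentiality_threshold)
        report = omics.filter_genes(
            expr, active_all[train], ess, essential,
            min_active_fraction=cfg.min_active_fraction, min_cv=cfg.min_cv,
            essential_rule=cfg.essential_rule,
        )
        active_f = active_all.loc[report.retained_expression]
        essential_f = essential.loc[report.retained_essentiality]

        target_union = set().union(*data.targets.targets.values())
        pathways = data.pathways
        if cfg.restrict_to_target_pathways:
            pathways = [pw for pw in pathways if pw.genes & target_union]

        pair_drugs = {
            row.pair_id: (row.drug_a, row.drug_b)
            for row in data.pairs.itertuples()
            if row.pair_id in set(selected)
        }
        status = synergy.set_index(["pair_id", "cell_line_id"])["status"]
        responses = {
            pid: pd.Series(
                [status.loc[(pid, c)] for c in train],
                index=pd.Index(train, name="cell_line_id"), dtype=int,
            )
            for pid in pair_drugs
        }

        ddp_frames, dd_frames = [], []
        for analysis in cfg.analyses:
            for mode in cfg.modes:
                ddp, dd = assoc.pathway_scan(
                    analysis, mode, pair_drugs, responses,
                    active_f[train], essential_f, data.targets, pathways,
                )
                ddp["analysis"], ddp["mode"] = analysis, mode
                dd["analysis"], dd["mode"] = analysis, mode
                ddp_frames.append(ddp)
                dd_frames.append(dd)
        ddp_df = pd.concat(ddp_frames, ignore_index=True) if ddp_frames else pd.DataFrame()
        dd_df = pd.concat(dd_frames, ignore_index=True) if dd_frames else pd.DataFrame()

        gene_fit, gene_overall = {}, {}
        if cfg.gene_level:
            for mode, matrix, genes in (
                ("expression", data.expression[train], report.retained_expression),
                ("essentiality", data.d2[train], report.retained_essentiality),
            ):
                fits, overall = assoc.gene_scan(mode, genes, matrix, responses)
                gene_fit[mode], gene_overall[mode] = fits, overall

        return SynergyAssociationResults(
            model=self,
            synergy=synergy,
            selected_pairs=selected,
            filter_report=report,
            pathways_used=pathways,
            pair_drugs=pair_drugs,
            responses=responses,
            active=active_f,
            ddp=ddp_df,
            dd=dd_df,
            gene_fits=gene_fit,
            gene_overall=gene_overall,
        )


@dataclass
class SynergyAssociationResults:
    """Fitted association scans plus the summaries derived from them."""

    model: SynergyAssociationModel
    synergy: pd.DataFrame
    selected_pairs: list[str]
    filter_report: omics.GeneFilterReport
    pathways_used: list[PathwaySet]
    pair_drugs: dict[str, tuple[str, str]]
    responses: dict[str, pd.Series]
    active: pd.DataFrame
    ddp: pd.DataFrame
    dd: pd.DataFrame
    gene_fits: dict[str, pd.DataFrame] = field(default_factory=dict)
    gene_overall: dict[str, pd.DataFrame] = field(default_factory=dict)

    # -- multiple-testing summaries --------------------------------------

    def n_tests(self, analysis: str, level: str) -> int:
        """Design size of a scan: pairs (DD) or pairs x pathways (DDP)."""
        n_pairs = len(self.selected_pairs)
        if level == "DD" or analysis == "PA1":
            return n_pairs
        return n_pairs * len(self.pathways_used)

    def fdr_table(self, analysis: str, level: str, mode: str) -> pd.DataFrame:
        """Expected/observed FDR table for one scan at the config thresholds."""
        cfg = self.model.config
        if level == "DD":
            sub = self.dd[(self.dd["analysis"] == analysis)
                          & (self.dd["mode"] == mode)]
            p = sub["overall_p"]
        else:
            sub = self.ddp[(self.ddp["analysis"] == analysis)
                           & (self.ddp["mode"] == mode)]
            p = sub["p_value"]
        return assoc.fdr_table(
            p, thresholds=cfg.fdr_thresholds,
            n_tests=self.n_tests(analysis, level),
            level=f"{analysis}/{level}/{mode}",
        )

    def all_fdr_tables(self) -> pd.DataFrame:
        cfg = self.model.config
        frames = []
        for analysis in cfg.analyses:
            levels = ("DD",) if analysis == "PA1" else ("DD", "DDP")
            for level in levels:
                for mode in cfg.modes:
                    frames.append(self.fdr_table(analysis, level, mode))
        return pd.concat(frames, ignore_index=True)

    def bonferroni(self, analysis: str, level: str = "DDP") -> float:
        return assoc.bonferroni_threshold(
            self.model.config.alpha, self.n_tests(analysis, level)
        )

    def overlap(self, analysis: str, level: str = "DD",
                threshold: float = 1e-3) -> tuple[int, int, int]:
        """Venn counts of expression- vs essentiality-significant units."""
        key, unit = (("dd", "pair_id") if level == "DD" else ("ddp", None))
        df = getattr(self, key)
        sub = df[df["analysis"] == analysis]
        if level == "DD":
            pe = sub[sub["mode"] == "expression"].set_index("pair_id")["overall_p"]
            ps = sub[sub["mode"] == "essentiality"].set_index("pair_id")["overall_p"]
        else:
            pe = sub[sub["mode"] == "expression"].set_index(
                ["pair_id", "unit_id"])["p_value"]
            ps = sub[sub["mode"] == "essentiality"].set_index(
                ["pair_id", "unit_id"])["p_value"]
        return assoc.significant_overlap(pe, ps, threshold)

    def modality_correlation(self, analysis: str, level: str = "DDP"
                             ) -> tuple[float, float]:
        """Pearson/Spearman correlation of expression vs essentiality p-values."""
        if level == "DD":
            sub = self.dd[self.dd["analysis"] == analysis]
            pe = sub[sub["mode"] == "expression"].set_index("pair_id")["overall_p"]
            ps = sub[sub["mode"] == "essentiality"].set_index("pair_id")["overall_p"]
        else:
            sub = self.ddp[self.ddp["analysis"] == analysis]
            pe = sub[sub["mode"] == "expression"].set_index(
                ["pair_id", "unit_id"])["p_value"]
            ps = sub[sub["mode"] == "essentiality"].set_index(
                ["pair_id", "unit_id"])["p_value"]
        return assoc.modality_correlation(pe, ps)

    def compare_target_groups(self, analysis: str = "PA2",
                              mode: str = "expression") -> dict:
        sub = self.ddp[(self.ddp["analysis"] == analysis)
                       & (self.ddp["mode"] == mode)]
        pw = {p.pathway_id: p for p in self.pathways_used}
        return assoc.compare_target_groups(
            sub, self.pair_drugs, self.model.data.targets, pathways=pw
        )

    # -- hold-out validation ---------------------------------------------

    def validate(self, top_k: int | None = None, analysis: str | None = None,
                 mode: str = "expression") -> pd.DataFrame:
        """Wilcoxon validation of the top DDP hits on both cohorts.

        Picks the ``top_k`` smallest DDP p-values of the given analysis
        (default: PA3 when fitted, else PA2) and mode, and compares the
        pathway active-gene count between synergy and no-synergy cell
        lines in the training and validation cohorts.
        """
        cfg = self.model.config
        top_k = top_k if top_k is not None else cfg.validate_top_k
        if analysis is None:
            analysis = "PA3" if "PA3" in set(self.ddp.get("analysis", [])) else "PA2"
        sub = self.ddp[(self.ddp["analysis"] == analysis)
                       & (self.ddp["mode"] == mode)].dropna(subset=["p_value"])
        top = sub.nsmallest(top_k, "p_value")
        pw_map = {p.pathway_id: p for p in self.pathways_used}
        status = self.synergy.set_index(["pair_id", "cell_line_id"])["status"]
        data = self.model.data
        rows = []
        for _, hit in top.iterrows():
            pw = pw_map[hit["unit_id"]]
            counts_all = (
                self.active.loc[self.active.index.isin(pw.genes)]
                .sum(axis=0)
                .astype(float)
            )
            for cohort, cells in (("train", data.train_cells),
                                  ("validation", data.valid_cells)):
                cells = [c for c in cells
                         if (hit["pair_id"], c) in status.index]
                s = pd.Series(
                    [status.loc[(hit["pair_id"], c)] for c in cells],
                    index=pd.Index(cells, name="cell_line_id"), dtype=int,
                )
                res = validate_pathway(hit["pair_id"], counts_all, s)
                rows.append({
                    "pair_id": hit["pair_id"], "pathway_id": pw.pathway_id,
                    "cohort": cohort, "n_synergy": res.n1,
                    "n_no_synergy": res.n2, "statistic": res.statistic,
                    "p": res.p_two_sided, "method": res.method,
                })
        return pd.DataFrame(rows)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Drug-combination synergy association scan",
            "=" * 46,
            f"training cell lines        {len(self.model.data.train_cells)}",
            f"validation cell lines      {len(self.model.data.valid_cells)}",
            f"drug pairs screened        {self.synergy['pair_id'].nunique()}",
            f"pairs selected (>= {cfg.min_synergistic} synergistic) "
            f"{len(self.selected_pairs)}",
            f"expression genes retained  {len(self.filter_report.retained_expression)}",
            f"essentiality genes retained {len(self.filter_report.retained_essentiality)}",
            f"pathways analysed          {len(self.pathways_used)}",
            "",
        ]
        if len(self.ddp):
            lines.append("scan          fits   non-NA   min p")
            for (analysis, mode), grp in self.ddp.groupby(["analysis", "mode"]):
                ok = grp["p_value"].dropna()
                mn = f"{ok.min():.3g}" if len(ok) else "NA"
                lines.append(
                    f"{analysis}/{mode:<12} {len(grp):>5} {len(ok):>7}   {mn}"
                )
        return "\n".join(lines)


def run_pipeline(config: PipelineConfig, base_dir: str | Path = ".",
                 out_dir: str | Path = "results") -> SynergyAssociationResults:
    """Run the full pipeline from input files and persist every stage table.

    Stage order: score -> select pairs -> filter genes -> features ->
    scans -> FDR -> validation; the run manifest is written last.
    """
    base, out = Path(base_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = SynergyAssociationModel.from_files(config, base)
    res = model.fit()

    fmt = "%.10g"
    res.synergy.to_csv(out / "synergy.tsv", sep="\t", index=False,
                       float_format=fmt, na_rep="NA")
    pd.DataFrame({"pair_id": res.selected_pairs}).to_csv(
        out / "selected_pairs.tsv", sep="\t", index=False)
    with open(out / "gene_filter_report.json", "w") as fh:
        json.dump({
            "retained_expression": res.filter_report.retained_expression,
            "retained_essentiality": res.filter_report.retained_essentiality,
            "excluded": res.filter_report.excluded,
        }, fh, indent=2)
    res.ddp.to_csv(out / "results_ddp.tsv", sep="\t", index=False,
                   float_format=fmt, na_rep="NA")
    res.dd.to_csv(out / "results_dd.tsv", sep="\t", index=False,
                  float_format=fmt, na_rep="NA")
    for mode, df in res.gene_fits.items():
        df.to_csv(out / f"results_gene_{mode}.tsv", sep="\t", index=False,
                  float_format=fmt, na_rep="NA")
        res.gene_overall[mode].to_csv(
            out / f"overall_gene_{mode}.tsv", sep="\t", index=False,
            float_format=fmt, na_rep="NA")
    res.all_fdr_tables().to_csv(out / "fdr_tables.tsv", sep="\t", index=False,
                                float_format=fmt, na_rep="NA")
    if model.data.valid_cells and len(res.ddp):
        res.validate().to_csv(out / "validation.tsv", sep="\t", index=False,
                              float_format=fmt, na_rep="NA")

    manifest = make_manifest(config, base)
    manifest.stage_counts = {
        "synergy_records": len(res.synergy),
        "selected_pairs": len(res.selected_pairs),
        "retained_expression_genes": len(res.filter_report.retained_expression),
        "retained_essentiality_genes": len(res.filter_report.retained_essentiality),
        "pathways": len(res.pathways_used),
        "ddp_fits": len(res.ddp),
    }
    manifest.write(out / "manifest.json")
    return res
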