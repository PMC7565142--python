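"""File formats, pipeline configuration, and the run manifest.

Matrix inputs are UTF-8 TSV with genes as rows and cell lines as
columns; dose-response data are long-format CSV of raw assay endpoints;
pathway gene sets use the standard GMT format; drug targets a two-column
long TSV.  NA is written as the literal ``NA``, decimals use ``.``.
Every writer's output round-trips through its reader.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import DrugTargetMap, PathwaySet
from .omics import EssentialityMatrix, ExpressionMatrix
from .scoring import GrowthFractionMatrix, RawEndpointRecord, growth_fraction
from .simulate import GroundTruth, StudyData

__all__ = [
    "DataError",
    "PipelineConfig",
    "RunManifest",
    "read_expression",
    "read_d2",
    "read_targets",
    "read_gmt",
    "read_dose_response",
    "read_cohorts",
    "read_inputs",
    "dose_response_to_matrices",
    "write_bundle",
    "write_truth",
    "write_gmt",
    "write_synergy",
    "read_synergy",
]

NA = "NA"
DOSE_COLUMNS = ["pair_id", "cell_line_id", "drug_a", "drug_b",
                "dose_index_a", "dose_index_b", "role", "value"]
DOSE_ROLES = {"mono_a", "mono_b", "combo", "control", "t0"}


class DataError(ValueError):
    """Malformed or mutually inconsistent input data."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and analysis selections for one pipeline run.

    All printed study constants are defaults here, never hard-coded in
    the stages: synergy threshold 10, essentiality threshold -0.5,
    presence fraction 0.2, CV floor 0.1, minimum synergistic cell lines
    5, FDR threshold grid {1e-4, 1e-3, 1e-2}, alpha 0.05.
    """

    expression: str = "expression.tsv"
    presence: str = "presence.tsv"
    d2: str = "d2.tsv"
    targets: str = "targets.tsv"
    pathways: str = "pathways.gmt"
    dose_response: str = "dose_response.csv"
    cohorts: str = "cohorts.tsv"

    synergy_threshold: float = 10.0
    essentiality_threshold: float = -0.5
    min_active_fraction: float = 0.2
    min_cv: float = 0.1
    min_synergistic: int = 5
    fdr_thresholds: tuple[float, ...] = (1e-4, 1e-3, 1e-2)
    alpha: float = 0.05
    essential_rule: str = "any"
    marginal_active: bool = False
    restrict_to_target_pathways: bool = True

    analyses: tuple[str, ...] = ("PA1", "PA2", "PA3")
    modes: tuple[str, ...] = ("expression", "essentiality", "combined")
    gene_level: bool = False
    validate_top_k: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.synergy_threshold < -100 or self.min_synergistic < 1:
            raise DataError("invalid scoring thresholds")
        if not (0 <= self.min_active_fraction <= 1):
            raise DataError("min_active_fraction must lie in [0, 1]")
        if not all(0 < t < 1 for t in self.fdr_thresholds):
            raise DataError("FDR thresholds must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise DataError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fdr_thresholds", "analyses", "modes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        data = asdict(self)
        for key in ("fdr_thresholds", "analyses", "modes"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class RunManifest:
    """Provenance record emitted on every pipeline run."""

    config_hash: str
    input_checksums: dict[str, str]
    versions: dict[str, str]
    stage_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def make_manifest(config: PipelineConfig, base_dir: Path) -> RunManifest:
    import scipy
    import statsmodels

    from . import __version__

    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()
    checksums = {}
    for name in ("expression", "presence", "d2", "targets", "pathways",
                 "dose_response", "cohorts"):
        p = base_dir / getattr(config, name)
        if p.exists():
            checksums[name] = sha256_file(p)
    return RunManifest(
        config_hash=cfg_hash,
        input_checksums=checksums,
        versions={
            "synerpath": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
    )


# --------------------------------------------------------------------------
# readers

def _read_matrix(path: str | Path, dtype=float) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA],
                     keep_default_na=False)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise DataError(f"{path}: duplicate gene rows {dups[:5]}")
    if dtype is float:
        try:
            df = df.astype(float)
        except ValueError as exc:
            raise DataError(f"{path}: non-numeric matrix entry ({exc})") from None
    return df


def read_expression(values_path: str | Path, presence_path: str | Path
                    ) -> ExpressionMatrix:
    values = _read_matrix(values_path)
    presence = _read_matrix(presence_path, dtype=str).astype(str)
    if values.shape != presence.shape or not values.index.equals(presence.index) \
            or not values.columns.equals(presence.columns):
        raise DataError(
            f"expression values ({values_path}: {values.shape}) and presence "
            f"calls ({presence_path}: {presence.shape}) do not share shape "
            "or labels"
        )
    try:
        return ExpressionMatrix(values=values, presence=presence)
    except ValueError as exc:
        raise DataError(f"{presence_path}: {exc}") from None


def read_d2(path: str | Path) -> EssentialityMatrix:
    try:
        return EssentialityMatrix(d2=_read_matrix(path))
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from None


def read_targets(path: str | Path) -> DrugTargetMap:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["drug_id", "gene_symbol"]:
        raise DataError(f"{path}: expected columns drug_id, gene_symbol")
    if df.duplicated().any():
        raise DataError(f"{path}: duplicate drug-target rows")
    mapping: dict[str, set[str]] = {}
    for drug, grp in df.groupby("drug_id"):
        mapping[str(drug)] = set(grp["gene_symbol"].astype(str))
    try:
        return DrugTargetMap(mapping)
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from None


def read_gmt(path: str | Path) -> list[PathwaySet]:
    pathways = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need pathway_id, description and at least one gene"
                )
            pid, desc, *genes = fields
            if pid in seen:
                raise DataError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            seen.add(pid)
            pathways.append(PathwaySet(pid, desc, frozenset(genes)))
    return pathways


def read_dose_response(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != DOSE_COLUMNS:
        raise DataError(f"{path}: expected columns {DOSE_COLUMNS}")
    bad = set(df["role"].unique()) - DOSE_ROLES
    if bad:
        raise DataError(f"{path}: unknown dose-response roles {sorted(bad)}")
    return df


def read_cohorts(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["cell_line_id", "cohort"]:
        raise DataError(f"{path}: expected columns cell_line_id, cohort")
    bad = set(df["cohort"].unique()) - {"train", "validation"}
    if bad:
        raise DataError(f"{path}: unknown cohort label(s) {sorted(bad)}")
    return df.set_index("cell_line_id")["cohort"]


def dose_response_to_matrices(df: pd.DataFrame
                              ) -> dict[tuple[str, str], GrowthFractionMatrix]:
    """Convert raw endpoints to growth-fraction grids per (pair, cell line).

    Each (pair, cell) block needs one ``t0`` and one ``control`` row;
    missing combination wells become NaN and are excluded from the score
    mean downstream.
    """
    out: dict[tuple[str, str], GrowthFractionMatrix] = {}
    for (pid, cell), grp in df.groupby(["pair_id", "cell_line_id"], sort=True):
        roles = grp["role"].to_numpy()
        values = grp["value"].to_numpy(dtype=float)
        ia = grp["dose_index_a"].to_numpy(dtype=int)
        ib = grp["dose_index_b"].to_numpy(dtype=int)
        for need in ("t0", "control"):
            if int((roles == need).sum()) != 1:
                raise DataError(
                    f"pair {pid!r} / cell {cell!r}: need exactly one "
                    f"{need!r} row"
                )
        t0 = float(values[roles == "t0"][0])
        t10 = float(values[roles == "control"][0])
        # validates t10 != t0 once for the whole block
        growth_fraction(RawEndpointRecord(t0=t0, t1=t0, t10=t10))
        gf = 100.0 * (values - t0) / (t10 - t0)

        ma, mb, co = roles == "mono_a", roles == "mono_b", roles == "combo"
        if not ma.any() or not mb.any():
            raise DataError(f"pair {pid!r} / cell {cell!r}: missing monotherapy rows")
        a_idx = np.sort(ia[ma])
        b_idx = np.sort(ib[mb])
        a_pos = {d: i for i, d in enumerate(a_idx)}
        b_pos = {d: i for i, d in enumerate(b_idx)}
        y_a = np.empty(len(a_idx))
        y_a[[a_pos[d] for d in ia[ma]]] = gf[ma]
        y_b = np.empty(len(b_idx))
        y_b[[b_pos[d] for d in ib[mb]]] = gf[mb]
        y_ab = np.full((len(a_idx), len(b_idx)), np.nan)
        y_ab[[a_pos[d] for d in ia[co]], [b_pos[d] for d in ib[co]]] = gf[co]
        out[(pid, cell)] = GrowthFractionMatrix(
            pair_id=pid, cell_line_id=cell, y_a=y_a, y_b=y_b, y_ab=y_ab
        )
    return out


def read_inputs(config: PipelineConfig, base_dir: str | Path = "."
                ) -> StudyData:
    """Read and cross-validate every pipeline input into a bundle.

    Enforces shared cell-line sets between expression and dose-response
    data, that dependency-score cell lines form a subset of expression
    cell lines, and that every drug appearing in the dose-response pairs
    has targets.
    """
    base = Path(base_dir)
    expr = read_expression(base / config.expression, base / config.presence)
    d2 = read_d2(base / config.d2)
    targets = read_targets(base / config.targets)
    pathways = read_gmt(base / config.pathways)
    dose = read_dose_response(base / config.dose_response)
    cohorts = read_cohorts(base / config.cohorts)

    expr_cells = set(expr.cell_lines)
    if not set(d2.cell_lines) <= expr_cells:
        raise DataError("dependency-score cell lines not present in expression data")
    if not set(cohorts.index) == expr_cells:
        raise DataError("cohort table does not cover the expression cell lines")
    dose_cells = set(dose["cell_line_id"].unique())
    if not dose_cells <= expr_cells:
        raise DataError("dose-response cell lines not present in expression data")
    pairs = dose[["pair_id", "drug_a", "drug_b"]].drop_duplicates("pair_id")
    for drug in sorted(set(pairs["drug_a"]) | set(pairs["drug_b"])):
        targets.targets_for(str(drug))  # raises UnknownDrugError if absent

    return StudyData(
        expression=expr.values, presence=expr.presence, d2=d2.d2,
        targets=targets, pathways=pathways, dose_response=dose,
        cohorts=cohorts, pairs=pairs.reset_index(drop=True),
    )


# --------------------------------------------------------------------------
# writers

_FLOAT_FMT = "%.10g"


def write_gmt(pathways: list[PathwaySet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.pathway_id, pw.name, *sorted(pw.genes)]) + "\n")


def write_bundle(bundle: StudyData, out_dir: str | Path,
                 config: PipelineConfig | None = None) -> None:
    """Write every pipeline input file of a study bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig()
    bundle.expression.to_csv(out / cfg.expression, sep="\t",
                             float_format=_FLOAT_FMT, na_rep=NA)
    bundle.presence.to_csv(out / cfg.presence, sep="\t", na_rep=NA)
    bundle.d2.to_csv(out / cfg.d2, sep="\t", float_format=_FLOAT_FMT, na_rep=NA)
    rows = [
        {"drug_id": d, "gene_symbol": g}
        for d in sorted(bundle.targets.targets)
        for g in sorted(bundle.targets.targets[d])
    ]
    pd.DataFrame(rows).to_csv(out / cfg.targets, sep="\t", index=False)
    write_gmt(bundle.pathways, out / cfg.pathways)
    bundle.dose_response.to_csv(out / cfg.dose_response, index=False,
                                float_format=_FLOAT_FMT)
    bundle.cohorts.reset_index().to_csv(out / cfg.cohorts, sep="\t", index=False)


def write_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
    truth.labels.to_csv(out / "truth_labels.tsv", sep="\t", index=False,
                        float_format=_FLOAT_FMT)
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False,
                       float_format=_FLOAT_FMT)
    with open(out / "truth_summary.json", "w") as fh:
        json.dump({"well_excursion_fraction": truth.well_excursion_fraction},
                  fh, indent=2)


def write_synergy(records, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"pair_id": r.pair_id, "cell_line_id": r.cell_line_id,
             "combo_score": r.combo_score, "status": r.status,
             "n_dose_pairs": r.n_dose_pairs}
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep=NA)


def read_synergy(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
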