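"""Per-pair logistic association scans and multiple-testing summaries.

For each selected drug pair a logistic regression relates the binary
synergy status across training cell lines to gene- or pathway-level
features.  Single-predictor models report the two-sided Wald p-value of
the slope; multi-predictor models report the likelihood-ratio p-value of
the full model against the intercept-only model.  With ~43 cell lines
and few synergistic ones, complete or quasi-complete separation and
non-convergence are expected occasionally; such fits fall back to
Firth-type penalized likelihood (Jeffreys-prior penalty) and report a
penalized likelihood-ratio p-value, flagged via ``converged``/``method``.

P-values are aggregated by taking minima: per gene over drug pairs
(gene scan), and per drug pair over pathways (DD level of the pathway
scan); the per (pair, pathway) p-values form the DDP level.  Summaries
include Bonferroni thresholds, expected/observed FDR tables, Venn-style
overlap counts between modalities, p-value correlations between
modalities, and target-vs-non-target group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import (
    DesignMatrix,
    DrugTargetMap,
    PathwaySet,
    assemble_design,
    type1_table,
    type2_table,
)
from .validation import wilcoxon_rank_sum

__all__ = [
    "AssociationResult",
    "fit_logistic",
    "firth_logistic",
    "gene_scan",
    "pathway_scan",
    "min_p",
    "bonferroni_threshold",
    "fdr_table",
    "significant_overlap",
    "modality_correlation",
    "compare_target_groups",
    "FDR_THRESHOLDS",
]

FDR_THRESHOLDS = (1e-4, 1e-3, 1e-2)

# |beta| on z-scored predictors beyond which an MLE fit is treated as
# separated (odds ratios beyond e^12 per SD are not estimable at n ~ 43).
_SEPARATION_BETA = 12.0
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class AssociationResult:
    """One fitted per-pair model.

    ``p_value`` is NaN when the design was degenerate, the response had a
    single class, or the fit failed; ``reason`` says which.  ``method``
    is ``wald``, ``lrt`` or ``firth_lrt`` for successful fits.
    """

    pair_id: str
    unit_id: str | None
    analysis: str
    mode: str
    p_value: float
    df: int
    converged: bool
    n_events: int
    method: str
    reason: str = ""


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def firth_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float, bool]:
    """Firth-penalized logistic regression via modified-score Newton steps.

    ``X`` must include the intercept column.  Returns the coefficient
    vector, the penalized log-likelihood (log-likelihood plus half the
    log-determinant of the Fisher information), and a convergence flag.
    The penalty keeps estimates finite under complete separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)

    def pll(b):
        p = 1.0 / (1.0 + np.exp(-(X @ b)))
        w = np.clip(p * (1 - p), 1e-12, None)
        info = X.T @ (X * w[:, None])
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf
        return _loglik(X, y, b) + 0.5 * logdet

    cur = pll(beta)
    converged = False
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        w = np.clip(p * (1 - p), 1e-12, None)
        info = X.T @ (X * w[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        # leverages of the weighted hat matrix
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # step-halving to guarantee penalized-likelihood ascent
        new = beta + step
        new_pll = pll(new)
        halvings = 0
        while new_pll < cur and halvings < 30:
            step *= 0.5
            new = beta + step
            new_pll = pll(new)
            halvings += 1
        beta, cur = new, new_pll
        if np.max(np.abs(score)) < tol or np.max(np.abs(step)) < tol:
            converged = True
            break
    return beta, cur, converged


def _firth_lrt_p(X1: np.ndarray, y: np.ndarray, k_slopes: int) -> tuple[float, bool]:
    """Penalized LRT p-value of the full model against intercept only."""
    _, pll_full, c1 = firth_logistic(X1, y)
    _, pll_null, c0 = firth_logistic(np.ones((len(y), 1)), y)
    lr = max(0.0, 2.0 * (pll_full - pll_null))
    p = float(stats.chi2.sf(lr, df=k_slopes))
    return max(p, _P_FLOOR), c1 and c0


def fit_logistic(design: DesignMatrix, unit_id: str | None = None) -> AssociationResult:
    """Fit one per-pair logistic model and extract its p-value.

    Single retained predictor: two-sided Wald p of the slope.  Several
    predictors: likelihood-ratio p against the intercept-only model.
    Detected separation or non-convergence triggers the Firth fallback
    (penalized LRT, ``method="firth_lrt"``).  Degenerate designs and
    single-class responses give NaN p-values with an explanatory reason.
    """
    y = design.y
    n_events = int(y.sum())
    base = dict(
        pair_id=design.pair_id,
        unit_id=unit_id,
        analysis=design.analysis,
        mode=design.mode,
        n_events=n_events,
    )
    if design.is_degenerate:
        return AssociationResult(
            p_value=np.nan, df=0, converged=False, method="na",
            reason="degenerate", **base,
        )
    if n_events == 0 or n_events == len(y):
        return AssociationResult(
            p_value=np.nan, df=0, converged=False, method="na",
            reason="no_events", **base,
        )

    Xs = design.X.to_numpy(dtype=float)
    k = Xs.shape[1]
    X1 = np.column_stack([np.ones(len(y)), Xs])

    needs_firth = False
    p_value = np.nan
    method = ""
    try:
        import statsmodels.api as sm

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.Logit(y, X1).fit(disp=0, maxiter=100, method="newton")
        msgs = " ".join(str(w.message) for w in caught)
        if (
            not res.mle_retvals.get("converged", False)
            or "separation" in msgs.lower()
            or np.max(np.abs(res.params[1:])) > _SEPARATION_BETA
            or not np.all(np.isfinite(res.bse))
        ):
            needs_firth = True
        else:
            if k == 1:
                p_value = float(res.pvalues[1])
                method = "wald"
            else:
                # intercept-only logistic MLE in closed form: p_hat = mean(y)
                ph = y.mean()
                ll0 = len(y) * (ph * np.log(ph) + (1 - ph) * np.log(1 - ph))
                lr = max(0.0, 2.0 * (res.llf - ll0))
                p_value = float(stats.chi2.sf(lr, df=k))
                method = "lrt"
            if not np.isfinite(p_value):
                needs_firth = True
    except Exception:
        needs_firth = True

    if needs_firth:
        p_value, conv = _firth_lrt_p(X1, y, k)
        return AssociationResult(
            p_value=max(p_value, _P_FLOOR), df=k, converged=conv,
            method="firth_lrt", reason="" if conv else "firth_not_converged",
            **base,
        )
    return AssociationResult(
        p_value=max(p_value, _P_FLOOR), df=k, converged=True, method=method, **base
    )


def _single_feature_design(
    pair_id: str, mode: str, values: pd.Series, response: pd.Series
) -> DesignMatrix:
    """One-column standardized design from a raw per-cell feature."""
    x = values.loc[response.index].astype(float)
    sd = x.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        X = pd.DataFrame(index=response.index)
        return DesignMatrix(pair_id, "gene", mode, X, response.to_numpy(float),
                            dropped_constant=["feature"])
    z = (x - x.mean()) / sd
    X = pd.DataFrame({"feature": z})
    return DesignMatrix(pair_id, "gene", mode, X, response.to_numpy(float))


def min_p(results: pd.DataFrame, by: str, unit: str = "unit_id") -> pd.DataFrame:
    """Minimum-p aggregation, ignoring NA p-values.

    Groups ``results`` by ``by`` and returns for each group the minimum
    ``p_value`` plus the identifier (column ``unit``) attaining it.
    Groups whose p-values are all NA keep an NA overall p.
    """
    rows = []
    for key, grp in results.groupby(by, sort=True):
        valid = grp.dropna(subset=["p_value"])
        if len(valid) == 0:
            rows.append({by: key, "overall_p": np.nan, "argmin": None})
        else:
            best = valid.iloc[int(np.argmin(valid["p_value"].to_numpy()))]
            rows.append({by: key, "overall_p": float(best["p_value"]),
                         "argmin": best[unit]})
    return pd.DataFrame(rows)


def gene_scan(
    mode: str,
    genes: Sequence[str],
    feature_matrix: pd.DataFrame,
    responses: Mapping[str, pd.Series],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-gene logistic scan across drug pairs.

    ``feature_matrix`` holds the raw per-gene feature (normalized
    expression or dependency score), genes x cell lines.  ``responses``
    maps pair_id -> binary synergy status indexed by training cell lines.
    Returns the per (gene, pair) results and the per-gene minimum-p
    aggregation over pairs.
    """
    recs = []
    for gene in genes:
        if gene not in feature_matrix.index:
            continue
        vals = feature_matrix.loc[gene]
        for pair_id, resp in responses.items():
            d = _single_feature_design(pair_id, mode, vals, resp)
            r = fit_logistic(d, unit_id=gene)
            recs.append(r)
    df = pd.DataFrame([r.__dict__ for r in recs])
    overall = min_p(df, by="unit_id", unit="pair_id") if len(df) else pd.DataFrame()
    return df, overall


def pathway_scan(
    analysis: str,
    mode: str,
    pair_drugs: Mapping[str, tuple[str, str]],
    responses: Mapping[str, pd.Series],
    active: pd.DataFrame,
    essential: pd.DataFrame,
    targets: DrugTargetMap,
    pathways: Sequence[PathwaySet],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One of the three pathway analyses for every selected drug pair.

    PA1 fits one target-feature model per pair (no pathway dimension);
    PA2 and PA3 fit one model per (pair, pathway).  Returns the
    DDP-level results (per pair-pathway; for PA1 the single per-pair
    model) and the DD-level minimum-p aggregation per pair.
    """
    recs: list[AssociationResult] = []
    t2_cache = {
        pw.pathway_id: type2_table(pw, active, essential) for pw in pathways
    }
    for pair_id, (da, db) in pair_drugs.items():
        resp = responses[pair_id]
        t1 = (
            type1_table(da, db, active, essential, targets,
                        cell_lines=list(resp.index))
            if analysis in ("PA1", "PA3")
            else None
        )
        if analysis == "PA1":
            design = assemble_design(pair_id, analysis, mode, t1, resp)
            recs.append(fit_logistic(design, unit_id=None))
        else:
            for pw in pathways:
                feats = t2_cache[pw.pathway_id].loc[list(resp.index)]
                if t1 is not None:
                    feats = pd.concat([t1, feats], axis=1)
                design = assemble_design(pair_id, analysis, mode, feats, resp)
                recs.append(fit_logistic(design, unit_id=pw.pathway_id))
    ddp = pd.DataFrame([r.__dict__ for r in recs])
    dd = min_p(ddp, by="pair_id", unit="unit_id") if len(ddp) else pd.DataFrame()
    return ddp, dd


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-corrected significance threshold alpha / m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def fdr_table(
    p_values: Iterable[float],
    thresholds: Sequence[float] = FDR_THRESHOLDS,
    n_tests: int | None = None,
    level: str | None = None,
) -> pd.DataFrame:
    """Expected/observed FDR table over a p-value collection.

    For each threshold t: observed = #{p <= t} among non-NA p-values;
    expected = t * n_tests rounded to two decimals (matching the
    precision at which such tables are printed); fdr = expected /
    observed, NA when nothing is observed.  ``fdr_raw`` uses the
    unrounded expected count.  ``n_tests`` defaults to the length of the
    p-value collection including NAs, i.e. the design size of the scan.
    """
    p = np.asarray(list(p_values), dtype=float)
    if n_tests is None:
        n_tests = p.size
    if n_tests < np.isfinite(p).sum():
        raise ValueError("n_tests smaller than the number of non-NA p-values")
    rows = []
    for t in thresholds:
        observed = int((p[np.isfinite(p)] <= t).sum())
        expected_raw = t * n_tests
        expected = round(expected_raw, 2)
        fdr = expected / observed if observed > 0 else np.nan
        fdr_raw = expected_raw / observed if observed > 0 else np.nan
        rows.append(
            {
                "level": level,
                "threshold": t,
                "n_observed": observed,
                "n_expected": expected,
                "fdr": fdr,
                "fdr_raw": fdr_raw,
                "n_tests": n_tests,
            }
        )
    return pd.DataFrame(rows)


def significant_overlap(
    p_expr: pd.Series,
    p_ess: pd.Series,
    threshold: float = 1e-3,
) -> tuple[int, int, int]:
    """Venn counts of units significant by expression and/or essentiality.

    Units are compared on the shared universe of the two series' indexes;
    NA p-values never count as significant.
    """
    sig_e = set(p_expr.index[(p_expr <= threshold).fillna(False)])
    sig_s = set(p_ess.index[(p_ess <= threshold).fillna(False)])
    both = sig_e & sig_s
    return len(sig_e - both), len(sig_s - both), len(both)


def modality_correlation(
    p_expr: pd.Series, p_ess: pd.Series
) -> tuple[float, float]:
    """Pearson r and Spearman rho of paired p-values across modalities.

    Pairs are matched on index; entries NA in either series are dropped.
    Fewer than 3 complete pairs yields (NaN, NaN).
    """
    df = pd.concat({"e": p_expr, "s": p_ess}, axis=1, join="inner").dropna()
    if len(df) < 3:
        return (np.nan, np.nan)
    r = stats.pearsonr(df["e"], df["s"]).statistic
    rho = stats.spearmanr(df["e"], df["s"]).statistic
    return float(r), float(rho)


def compare_target_groups(
    results: pd.DataFrame,
    pair_drugs: Mapping[str, tuple[str, str]],
    targets: DrugTargetMap,
    pathways: Mapping[str, PathwaySet] | None = None,
) -> dict:
    """Compare -log10 p between target and non-target units.

    Each (pair, unit) result is labeled *target* when the unit gene
    belongs to the pair's target union, or — when ``pathways`` is given
    and units are pathway ids — when the pathway contains at least one
    target of the pair.  Returns per-group quartiles of -log10 p and a
    two-sided rank-sum p comparing the groups (NaN when a group is
    empty).
    """
    valid = results.dropna(subset=["p_value"])
    labels = []
    for _, row in valid.iterrows():
        union = targets.pair_union(*pair_drugs[row["pair_id"]])
        unit = row["unit_id"]
        if pathways is not None:
            is_target = bool(pathways[unit].genes & union)
        else:
            is_target = unit in union
        labels.append(is_target)
    neglog = -np.log10(valid["p_value"].to_numpy(dtype=float))
    lab = np.asarray(labels, dtype=bool)
    tgt, non = neglog[lab], neglog[~lab]

    def quartiles(v):
        if v.size == 0:
            return (np.nan, np.nan, np.nan)
        return tuple(float(q) for q in np.percentile(v, [25, 50, 75]))

    if tgt.size == 0 or non.size == 0:
        p = np.nan
    else:
        p = wilcoxon_rank_sum(tgt, non).p_two_sided
    return {
        "n_target": int(tgt.size),
        "n_non_target": int(non.size),
        "target_quartiles": quartiles(tgt),
        "non_target_quartiles": quartiles(non),
        "rank_sum_p": p,
    }
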