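"""Logistic fits, Firth fallback, min-p aggregation and FDR summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

from synerpath.association import (
    bonferroni_threshold,
    fdr_table,
    firth_logistic,
    fit_logistic,
    gene_scan,
    min_p,
    modality_correlation,
    significant_overlap,
)
from synerpath.features import DesignMatrix


def make_design(x, y, pair="p"):
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    cols = [f"x{i}" for i in range(x.shape[1])]
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    X = pd.DataFrame(z, columns=cols,
                     index=pd.Index([f"c{i}" for i in range(len(x))],
                                    name="cell_line_id"))
    return DesignMatrix(pair, "PA2", "expression", X,
                        np.asarray(y, dtype=float))


def irls_logit(X1, y, maxiter=200, tol=1e-12):
    """Independent IRLS maximum-likelihood oracle."""
    beta = np.zeros(X1.shape[1])
    for _ in range(maxiter):
        eta = X1 @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        XtWX = X1.T @ (X1 * W[:, None])
        step = np.linalg.solve(XtWX, X1.T @ (y - p))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X1 @ beta
    ll = float(y @ eta - np.logaddexp(0, eta).sum())
    cov = np.linalg.inv(XtWX)
    return beta, cov, ll


def test_degenerate_design_gives_na():
    X = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(6)]))
    d = DesignMatrix("p", "PA2", "expression", X, np.array([0, 1, 0, 1, 0, 1.0]))
    r = fit_logistic(d)
    assert np.isnan(r.p_value) and r.reason == "degenerate"


def test_single_class_response_gives_na():
    r = fit_logistic(make_design(np.arange(6.0), np.zeros(6)))
    assert np.isnan(r.p_value) and r.reason == "no_events"


def test_wald_p_matches_irls_oracle(rng):
    n = 60
    x = rng.normal(size=n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * x - 0.3)))).astype(float)
    r = fit_logistic(make_design(x, y))
    assert r.method == "wald" and r.df == 1

    z = (x - x.mean()) / x.std()
    X1 = np.column_stack([np.ones(n), z])
    beta, cov, _ = irls_logit(X1, y)
    wald = beta[1] / np.sqrt(cov[1, 1])
    p_oracle = 2 * stats.norm.sf(abs(wald))
    assert r.p_value == pytest.approx(p_oracle, abs=1e-6)


def test_lrt_p_matches_irls_oracle(rng):
    n = 60
    X = rng.normal(size=(n, 3))
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.4 * X[:, 0] - 0.2)))).astype(float)
    r = fit_logistic(make_design(X, y))
    assert r.method == "lrt" and r.df == 3

    z = (X - X.mean(axis=0)) / X.std(axis=0)
    X1 = np.column_stack([np.ones(n), z])
    _, _, ll = irls_logit(X1, y)
    ph = y.mean()
    ll0 = n * (ph * np.log(ph) + (1 - ph) * np.log(1 - ph))
    p_oracle = stats.chi2.sf(2 * (ll - ll0), df=3)
    assert r.p_value == pytest.approx(p_oracle, abs=1e-6)


def penalized_ll(X1, y, beta):
    """Independent Jeffreys-penalized log-likelihood for the Firth oracle."""
    eta = X1 @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    ll = float(y @ eta - np.logaddexp(0, eta).sum())
    info = X1.T @ (X1 * (p * (1 - p))[:, None])
    sign, logdet = np.linalg.slogdet(info)
    return ll + 0.5 * logdet if sign > 0 else -np.inf


def test_separated_data_falls_back_to_firth():
    x = np.arange(1.0, 7.0)
    y = np.array([0, 0, 0, 1, 1, 1.0])
    r = fit_logistic(make_design(x, y))
    assert r.method == "firth_lrt"
    assert 0 < r.p_value < 1 and np.isfinite(r.p_value)

    # oracle: coarse grid then simplex refinement of the penalized likelihood
    z = (x - x.mean()) / x.std()
    X1 = np.column_stack([np.ones(6), z])
    grid = [np.array([b0, b1]) for b0 in np.linspace(-4, 4, 41)
            for b1 in np.linspace(-4, 8, 61)]
    best = max(grid, key=lambda b: penalized_ll(X1, y, b))
    full = minimize(lambda b: -penalized_ll(X1, y, b), best,
                    method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    X0 = np.ones((6, 1))
    b0s = np.linspace(-4, 4, 81)
    best0 = max(b0s, key=lambda b0: penalized_ll(X0, y, np.array([b0])))
    null = minimize(lambda b: -penalized_ll(X0, y, b), [best0],
                    method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    lr = 2 * (-full.fun - -null.fun)
    p_oracle = stats.chi2.sf(lr, df=1)
    assert r.p_value == pytest.approx(p_oracle, rel=1e-4)


def test_firth_estimates_finite_and_ascending(rng):
    x = np.concatenate([rng.normal(-2, 0.5, 10), rng.normal(2, 0.5, 10)])
    y = np.concatenate([np.zeros(10), np.ones(10)])
    X1 = np.column_stack([np.ones(20), (x - x.mean()) / x.std()])
    beta, pll, conv = firth_logistic(X1, y)
    assert conv and np.all(np.isfinite(beta))
    assert pll >= penalized_ll(X1, y, np.zeros(2)) - 1e-9


def test_min_p_aggregation_rules():
    df = pd.DataFrame({
        "unit_id": ["g1"] * 3 + ["g2"] * 2,
        "pair_id": ["a", "b", "c", "a", "b"],
        "p_value": [0.3, 0.01, 0.2, np.nan, np.nan],
    })
    overall = min_p(df, by="unit_id", unit="pair_id").set_index("unit_id")
    assert overall.loc["g1", "overall_p"] == pytest.approx(0.01)
    assert overall.loc["g1", "argmin"] == "b"
    assert np.isnan(overall.loc["g2", "overall_p"])


def test_min_p_never_exceeds_contributors_and_monotone(rng):
    ps = rng.random(20)
    df = pd.DataFrame({"unit_id": "g", "pair_id": range(20), "p_value": ps})
    overall = min_p(df, by="unit_id", unit="pair_id")
    assert overall["overall_p"].iloc[0] <= ps.min() + 1e-15
    # adding a pair can only lower the minimum
    df2 = pd.concat([df, pd.DataFrame({"unit_id": ["g"], "pair_id": [99],
                                       "p_value": [ps.min() / 2]})])
    overall2 = min_p(df2, by="unit_id", unit="pair_id")
    assert overall2["overall_p"].iloc[0] <= overall["overall_p"].iloc[0]


def test_gene_scan_min_over_pairs(rng):
    genes = ["g1", "g2"]
    cells = [f"c{i}" for i in range(40)]
    fm = pd.DataFrame(rng.normal(size=(2, 40)), index=genes, columns=cells)
    y1 = pd.Series((fm.loc["g1"] > 0).astype(int).to_numpy(), index=cells)
    y2 = pd.Series(rng.integers(0, 2, size=40), index=cells)
    fits, overall = gene_scan("expression", genes, fm, {"pA": y1, "pB": y2})
    assert len(fits) == 4
    ov = overall.set_index("unit_id")
    g1 = fits[(fits.unit_id == "g1")].dropna(subset=["p_value"])
    assert ov.loc["g1", "overall_p"] == pytest.approx(g1["p_value"].min())


@pytest.mark.parametrize(
    "alpha,m,expected",
    [(0.05, 3024, 0.05 / 3024), (0.05, 18810, 0.05 / 18810), (0.05, 1, 0.05)],
)
def test_bonferroni_threshold(alpha, m, expected):
    t = bonferroni_threshold(alpha, m)
    assert t == pytest.approx(expected)
    if m == 3024:
        assert t == pytest.approx(1.653e-5, rel=1e-3)
    if m == 18810:
        assert t == pytest.approx(2.6582e-6, rel=1e-4)


def test_fdr_table_rounding_and_na():
    # 62 of 114 drug-pair p-values at or below 1e-3
    p = np.concatenate([np.full(62, 5e-4), np.full(52, 0.5)])
    t = fdr_table(p, thresholds=[1e-3], n_tests=114).iloc[0]
    assert t["n_observed"] == 62
    assert t["n_expected"] == pytest.approx(0.11)
    assert t["fdr"] == pytest.approx(1.77e-3, rel=5e-3)
    empty = fdr_table(np.full(114, 0.5), thresholds=[1e-3], n_tests=114).iloc[0]
    assert empty["n_observed"] == 0 and np.isnan(empty["fdr"])


def test_fdr_observed_matches_naive_scan(rng):
    p = rng.random(500)
    p[rng.choice(500, 20, replace=False)] = np.nan
    tab = fdr_table(p, thresholds=[1e-3, 1e-2, 0.05, 0.2], n_tests=500)
    for _, row in tab.iterrows():
        naive = sum(1 for v in p if np.isfinite(v) and v <= row["threshold"])
        assert row["n_observed"] == naive


def test_fdr_na_excluded_but_counted_in_design():
    p = [0.0005, np.nan, 0.5]
    tab = fdr_table(p, thresholds=[1e-3], n_tests=3).iloc[0]
    assert tab["n_observed"] == 1 and tab["n_tests"] == 3
    with pytest.raises(ValueError):
        fdr_table([0.1, 0.2], thresholds=[1e-3], n_tests=1)


def test_significant_overlap_counts():
    pe = pd.Series({"a": 1e-4, "b": 5e-4, "c": 0.5})
    ps = pd.Series({"b": 1e-4, "c": 1e-4, "d": 0.9})
    # shared universe {b, c}: expr-only a is outside ess universe but still
    # significant by expression
    n_e, n_s, n_both = significant_overlap(pe, ps, threshold=1e-3)
    assert (n_e, n_s, n_both) == (1, 1, 1)
    assert significant_overlap(pd.Series({"a": 1e-4}), pd.Series({"b": 1e-4})) == (1, 1, 0)
    same = pd.Series({"a": 1e-4, "b": 1e-4})
    assert significant_overlap(same, same) == (0, 0, 2)


def test_modality_correlation_basic(rng):
    p = pd.Series(rng.random(50))
    r, rho = modality_correlation(p, p)
    assert r == pytest.approx(1.0) and rho == pytest.approx(1.0)
    rev = pd.Series(np.sort(rng.random(50)))
    fwd = pd.Series(rev.to_numpy()[::-1], index=rev.index)
    _, rho2 = modality_correlation(rev, fwd)
    assert rho2 == pytest.approx(-1.0)
    assert np.isnan(modality_correlation(p.iloc[:2], p.iloc[:2])[0])


def test_modality_correlation_null_bound():
    r_ = np.random.default_rng(42)
    a = pd.Series(r_.random(1000))
    b = pd.Series(r_.random(1000))
    r, rho = modality_correlation(a, b)
    assert abs(r) < 0.07 and abs(rho) < 0.07
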