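"""Phenotype-association regressions: OLS engine, M1 and M2 partial F tests."""

import numpy as np
import pytest
from scipy import stats

from degpag import SingularDesignError, fit_ols, pag_m1, pag_m2
from degpag.datasets import generate_fixture
from degpag.pag import m1_pvalues_arrays, m2_pvalues_arrays

from conftest import build_dataset

GROUP33 = np.array([0, 0, 0, 1, 1, 1])


class TestFitOls:
    def test_constant_fit(self):
        fit = fit_ols(np.full(5, 5.0), np.ones((5, 1)))
        assert fit.coefficients[0] == pytest.approx(5.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.loglik == np.inf

    def test_noiseless_line(self):
        x = np.arange(6.0)
        fit = fit_ols(2.0 + 3.0 * x, np.column_stack([np.ones(6), x]))
        np.testing.assert_allclose(fit.coefficients, [2.0, 3.0], rtol=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_on_fixed_fixture(self):
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.5])
        x = np.array([0.5, 1.0, 1.5, 2.5, 3.0, 4.0])
        X = np.column_stack([np.ones(6), x])
        fit = fit_ols(y, X)
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # closed-form oracle
        np.testing.assert_allclose(fit.coefficients, beta, rtol=1e-10)
        rss = float((y - X @ beta) @ (y - X @ beta))
        assert fit.rss == pytest.approx(rss, rel=1e-10)
        assert fit.loglik == pytest.approx(-3.0 * (np.log(2 * np.pi * rss / 6) + 1))

    def test_singular_design_names_offending_column(self):
        X = np.column_stack([np.ones(5), np.full(5, 2.0)])
        with pytest.raises(SingularDesignError) as err:
            fit_ols(np.arange(5.0), X)
        assert err.value.column == 1

    def test_nesting_monotonicity(self, rng):
        y = rng.normal(0, 1, 20)
        X = np.column_stack([np.ones(20), rng.normal(0, 1, 20)])
        X2 = np.column_stack([X, rng.normal(0, 1, 20)])
        assert fit_ols(y, X2).rss <= fit_ols(y, X).rss + 1e-12


def _anova_f_oracle(y, X_full, X_red):
    """Partial F via explicit sums-of-squares decomposition."""
    def rss(X):
        b = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ b
        return float(r @ r)

    rf, rr = rss(X_full), rss(X_red)
    df2 = len(y) - X_full.shape[1]
    F = (rr - rf) / (rf / df2)
    return F, stats.f.sf(F, 1, df2)


def test_m1_matches_anova_oracle_on_nine_samples():
    pheno = np.array([21.0, 30.0, 18.0, 40.0, 35.0, 27.0, 45.0, 33.0, 25.0])
    x = np.array([7.1, 7.9, 6.8, 8.8, 8.3, 7.5, 9.4, 8.0, 7.2])
    group = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1])
    expr, design = build_dataset([x], group, phenotype=pheno)
    res = pag_m1(expr, design)
    n = 9
    F, p = _anova_f_oracle(
        pheno, np.column_stack([np.ones(n), x]), np.ones((n, 1))
    )
    assert res.loc[0, "statistic"] == pytest.approx(F, rel=1e-10)
    assert res.loc[0, "pvalue"] == pytest.approx(p, rel=1e-10)
    # and for M2, adjusting for group, df = (1, n-3)
    res2 = pag_m2(expr, design)
    F2, p2 = _anova_f_oracle(
        pheno,
        np.column_stack([np.ones(n), x, group]),
        np.column_stack([np.ones(n), group]),
    )
    assert res2.loc[0, "statistic"] == pytest.approx(F2, rel=1e-10)
    assert res2.loc[0, "pvalue"] == pytest.approx(p2, rel=1e-10)


def test_m1_m2_match_statsmodels(rng):
    sm = pytest.importorskip("statsmodels.api")
    group = np.array([0] * 6 + [1] * 6)
    pheno = rng.normal(25, 16, 12)
    values = rng.normal(0, 1, (5, 12))
    _, p1 = m1_pvalues_arrays(values, pheno)
    _, p2 = m2_pvalues_arrays(values, pheno, group)
    for i in range(5):
        X1 = sm.add_constant(values[i])
        m1 = sm.OLS(pheno, X1).fit()
        assert p1[i] == pytest.approx(m1.pvalues[1], rel=1e-8)
        X2 = sm.add_constant(np.column_stack([values[i], group]))
        m2 = sm.OLS(pheno, X2).fit()
        assert p2[i] == pytest.approx(m2.pvalues[1], rel=1e-8)


def test_m1_perfect_association_and_null_uniformity(rng):
    x = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 9.0])
    expr, design = build_dataset([x], GROUP33, phenotype=2.0 * x - 1.0)
    res = pag_m1(expr, design)
    assert res.loc[0, "pvalue"] == 0.0  # rss_full = 0 handled as maximal F
    # under the null (phenotype independent of expression) p is Uniform(0,1)
    pvals = []
    for _ in range(1000):
        v = rng.normal(0, 1, (1, 20))
        _, p = m1_pvalues_arrays(v, rng.normal(0, 1, 20))
        pvals.append(p[0])
    assert stats.kstest(pvals, "uniform").pvalue > 1e-3


def test_m2_collinear_with_group_gives_nan():
    # expression constant within each group: collinear with the group column
    x = np.array([1.0, 1.0, 1.0, 4.0, 4.0, 4.0])
    expr, design = build_dataset([x], GROUP33, phenotype=[3, 1, 2, 6, 4, 5.0])
    assert np.isnan(pag_m2(expr, design).loc[0, "pvalue"])


def test_m2_equals_m1_when_group_orthogonal(rng):
    # identical group means in phenotype and expression: the group column
    # explains nothing, so adjusting for it leaves the slope test unchanged
    base_x = rng.normal(0, 1, 3)
    base_p = rng.normal(0, 1, 3)
    x = np.concatenate([base_x, base_x])
    pheno = np.concatenate([base_p, base_p])
    expr, design = build_dataset([x], GROUP33, phenotype=pheno)
    p1 = pag_m1(expr, design).loc[0, "pvalue"]
    p2 = pag_m2(expr, design).loc[0, "pvalue"]
    f1 = pag_m1(expr, design).loc[0, "statistic"]
    f2 = pag_m2(expr, design).loc[0, "statistic"]
    # same R^2; only the error df differs between the two F tests
    assert f2 == pytest.approx(f1 * 3 / 4, rel=1e-9)
    assert p2 == pytest.approx(
        stats.f.sf(f1 * 3 / 4, 1, 3), rel=1e-9
    ) and p1 == pytest.approx(stats.f.sf(f1, 1, 4), rel=1e-9)


def test_crossing_pattern_missed_by_m1_found_by_m2():
    """Group shift cancels the marginal slope; only the adjusted model sees it."""
    expr, design, planted = generate_fixture("v1rh4_pattern", n_genes=30, seed=3)
    m1 = pag_m1(expr, design).set_index("gene_id")
    m2 = pag_m2(expr, design).set_index("gene_id")
    for g in planted:
        assert m1.loc[g, "pvalue"] > 0.05
        assert m2.loc[g, "pvalue"] < 0.05


def test_f_invariant_to_affine_rescaling_of_expression(rng):
    values = rng.normal(5, 2, (10, 12))
    pheno = rng.normal(25, 16, 12)
    group = np.array([0] * 6 + [1] * 6)
    f_a, _ = m1_pvalues_arrays(values, pheno)
    f_b, _ = m1_pvalues_arrays(3.5 * values - 11.0, pheno)
    np.testing.assert_allclose(f_a, f_b, rtol=1e-9)
    g_a, _ = m2_pvalues_arrays(values, pheno, group)
    g_b, _ = m2_pvalues_arrays(-0.5 * values + 4.0, pheno, group)
    np.testing.assert_allclose(g_a, g_b, rtol=1e-9)
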