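"""Joint identification of genes that are both DEGs and PAGs.

Three strategies:

* ``naive_joint`` — intersect the genes significant in a DEG test and in a
  PAG regression, each run on all genes.
* ``hierarchical_joint`` — two-stage screening: select at stage 1, re-test
  only the survivors at stage 2 (q-values, when used, recomputed within the
  survivor subset).
* ``model_based_test`` — a one-step intersection-union likelihood-ratio
  test on the joint model

      M3:  expression = g0 + g1 * group + g2 * phenotype + e

  of the composite null H0: g1 = 0 or g2 = 0 against H1: both nonzero. Each
  component LRT is n * log(rss_reduced / rss_full) under the profile
  Gaussian likelihood; the test statistic is Lambda = min of the two and is
  referred to the chi-square(1) upper tail. Because Lambda is never larger
  than either component LRT, the chi-square(1) calibration is conservative
  on the null axes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, StudyDesign, check_aligned
from .deg import ttest_deg
from .multitest import bh_qvalues
from .pag import pag_m1, pag_m2

__all__ = [
    "model_based_test",
    "model_lrt_arrays",
    "naive_joint",
    "hierarchical_joint",
]

_PAG_MODELS = {"m1": pag_m1, "m2": pag_m2}
_DEG_METHODS = {"ttest": ttest_deg}


def _rss_multi(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each row of Y regressed on X."""
    beta, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    return np.einsum("ij,ij->j", resid, resid)


def model_lrt_arrays(values: np.ndarray, group: np.ndarray, phenotype: np.ndarray):
    """Component LRTs, Lambda and p per gene row.

    Returns ``(lrt_gamma1, lrt_gamma2, lam, p)``. Constant genes give NaN
    throughout. For a perfect full-model fit (rss_full = 0) on a
    non-constant gene, each component LRT is +inf unless its reduced model
    also fits perfectly (then 0); Lambda = +inf with p = 0 only when both
    constrained fits are strictly worse than the (perfect) full fit.
    """
    n = values.shape[1]
    if n < 4:
        raise ValueError("the joint model needs at least 4 samples")
    if np.ptp(phenotype) == 0.0:
        raise ValueError("phenotype is constant")
    ones = np.ones(n)
    X_full = np.column_stack([ones, group, phenotype])
    X_g1_0 = np.column_stack([ones, phenotype])  # gamma1 constrained to 0
    X_g2_0 = np.column_stack([ones, group])  # gamma2 constrained to 0

    rss_full = _rss_multi(X_full, values)
    rss_g1_0 = _rss_multi(X_g1_0, values)
    rss_g2_0 = _rss_multi(X_g2_0, values)

    tss = np.einsum(
        "ij,ij->i", values - values.mean(axis=1, keepdims=True),
        values - values.mean(axis=1, keepdims=True),
    )
    constant = tss == 0.0
    tol = np.finfo(float).eps * 1e4 * np.maximum(tss, 1e-300)
    perfect = (rss_full <= tol) & ~constant

    with np.errstate(divide="ignore", invalid="ignore"):
        lrt1 = n * np.log(rss_g1_0 / rss_full)
        lrt2 = n * np.log(rss_g2_0 / rss_full)
    lrt1 = np.clip(lrt1, 0.0, None)  # nesting guarantees rss_reduced >= rss_full
    lrt2 = np.clip(lrt2, 0.0, None)
    # perfect full fit: a component LRT is +inf unless its reduced fit is
    # itself perfect, in which case dropping the term costs nothing
    lrt1[perfect] = np.where(rss_g1_0[perfect] <= tol[perfect], 0.0, np.inf)
    lrt2[perfect] = np.where(rss_g2_0[perfect] <= tol[perfect], 0.0, np.inf)
    lrt1[constant] = np.nan
    lrt2[constant] = np.nan
    lam = np.minimum(lrt1, lrt2)
    p = np.where(np.isnan(lam), np.nan, stats.chi2.sf(lam, df=1))
    return lrt1, lrt2, lam, p


def model_based_test(
    expr: ExpressionMatrix, design: StudyDesign, report_q: bool = False
) -> pd.DataFrame:
    """Intersection-union LRT per gene.

    Returns a table with columns gene_id, lambda, lrt_gamma1, lrt_gamma2,
    pvalue (and qvalue when ``report_q``), in input gene order.
    """
    check_aligned(expr, design)
    lrt1, lrt2, lam, p = model_lrt_arrays(
        expr.values, design.group, design.phenotype
    )
    out = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "method": "m3",
            "lambda": lam,
            "lrt_gamma1": lrt1,
            "lrt_gamma2": lrt2,
            "pvalue": p,
        }
    )
    if report_q:
        out["qvalue"] = bh_qvalues(out["pvalue"].to_numpy())
    return out


def _significant(results: pd.DataFrame, alpha: float, use_q: bool) -> set:
    if use_q:
        if "qvalue" in results.columns and results["qvalue"].notna().any():
            col = results["qvalue"].to_numpy(dtype=float)
        else:
            col = bh_qvalues(results["pvalue"].to_numpy(dtype=float))
    else:
        col = results["pvalue"].to_numpy(dtype=float)
    mask = col < alpha  # NaN compares False: degenerate genes never called
    return set(np.asarray(results["gene_id"])[mask])


def naive_joint(
    deg_results: pd.DataFrame,
    pag_results: pd.DataFrame,
    alpha: float = 0.05,
    use_q: bool = False,
) -> set:
    """Genes significant in BOTH the DEG and the PAG test at level alpha."""
    if set(deg_results["gene_id"]) != set(pag_results["gene_id"]):
        raise ValueError("DEG and PAG results cover different gene universes")
    return _significant(deg_results, alpha, use_q) & _significant(
        pag_results, alpha, use_q
    )


def hierarchical_joint(
    expr: ExpressionMatrix,
    design: StudyDesign,
    deg_method: str = "ttest",
    pag_model: str = "m1",
    alpha: float = 0.05,
    use_q: bool = False,
    order: str = "deg_first",
) -> set:
    """Two-stage screen: stage-1 selection, stage-2 re-test of survivors only.

    With raw p-value thresholds at both stages this returns exactly the
    naive intersection (per-gene p-values do not change when the gene set is
    subset); with q-value thresholds the stage-2 BH correction is computed
    within the survivor subset, which is where the two approaches part ways.
    """
    if order not in ("deg_first", "pag_first"):
        raise ValueError(f"unknown order {order!r}")
    if deg_method not in _DEG_METHODS:
        raise ValueError(
            f"deg_method must be one of {sorted(_DEG_METHODS)} (SAM calls genes by "
            "delta/FDR, not per-gene p-values, and cannot feed a threshold stage)"
        )
    if pag_model not in _PAG_MODELS:
        raise ValueError(f"pag_model must be one of {sorted(_PAG_MODELS)}")

    deg_fn = _DEG_METHODS[deg_method]
    pag_fn = _PAG_MODELS[pag_model]
    stage1_fn, stage2_fn = (
        (deg_fn, pag_fn) if order == "deg_first" else (pag_fn, deg_fn)
    )

    survivors = _significant(stage1_fn(expr, design), alpha, use_q)
    if not survivors:
        return set()
    stage2 = stage2_fn(expr, design)
    stage2 = stage2[stage2["gene_id"].isin(survivors)].reset_index(drop=True)
    if use_q:  # recompute BH within the screened subset
        stage2 = stage2.drop(columns=["qvalue"], errors="ignore")
    return _significant(stage2, alpha, use_q)
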