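"""Phenotype-association regressions.

Two Gaussian linear models are fitted per gene, with the continuous
phenotype as the response and the gene's expression as a covariate:

    M1:  phenotype = b0 + b1 * expression + e
    M2:  phenotype = b0 + b1 * expression + b2 * group + e

and the null b1 = 0 is tested by the partial F statistic (the squared slope
t), df = (1, n-2) for M1 and (1, n-3) for M2. M1 captures the marginal
expression effect; M2 the effect conditional on group, which matters when a
group shift masks (or fakes) the marginal slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, StudyDesign, check_aligned

__all__ = [
    "OlsFit",
    "SingularDesignError",
    "fit_ols",
    "pag_m1",
    "pag_m2",
    "m1_pvalues_arrays",
    "m2_pvalues_arrays",
]

_RANK_TOL = 1e-10


class SingularDesignError(ValueError):
    """Rank-deficient design matrix; carries the offending column index."""

    def __init__(self, column: int):
        self.column = column
        super().__init__(f"design matrix is rank deficient at column {column}")


@dataclass
class OlsFit:
    """Least-squares fit summary.

    ``loglik`` is the profile Gaussian log-likelihood
    -(n/2) * (log(2*pi*rss/n) + 1), +inf for a perfect (rss = 0) fit.
    """

    coefficients: np.ndarray
    rss: float
    n: int
    k: int
    loglik: float


def fit_ols(response: np.ndarray, covariates: np.ndarray) -> OlsFit:
    """Ordinary least squares of ``response`` on ``covariates`` (incl. intercept).

    Raises :class:`SingularDesignError` naming the first column whose
    R-diagonal in a QR factorization collapses when the design is rank
    deficient.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("covariates must be (n, k) matching response length")
    n, k = X.shape
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.max() > 0 else 1.0
    small = np.where(diag < _RANK_TOL * scale)[0]
    if small.size:
        raise SingularDesignError(int(small[0]))
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    loglik = np.inf if rss <= 0 else -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    return OlsFit(coefficients=beta, rss=rss, n=n, k=k, loglik=loglik)


def _slope_f(px: np.ndarray, py: np.ndarray, df2: int):
    """F for the slope of py on each row of px (both already residualized).

    Returns (F, p); rows with (near-)zero variation in px give NaN.
    """
    sxx = np.einsum("ij,ij->i", px, px)
    syy = float(py @ py)
    sxy = px @ py
    scale = np.max(np.abs(px), axis=1) ** 2 * px.shape[1]
    degenerate = sxx <= np.finfo(float).eps * 1e4 * np.maximum(scale, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.clip(sxy**2 / (sxx * syy), 0.0, 1.0)
        F = r2 / (1.0 - r2) * df2
    F = np.where(degenerate, np.nan, F)
    p = np.where(np.isnan(F), np.nan, stats.f.sf(F, 1, df2))
    p = np.where(np.isinf(F), 0.0, p)
    return F, p


def m1_pvalues_arrays(values: np.ndarray, phenotype: np.ndarray):
    """Marginal slope F-test per gene row; returns (F, p), df = (1, n-2)."""
    n = values.shape[1]
    if n < 3:
        raise ValueError("M1 needs at least 3 samples")
    px = values - values.mean(axis=1, keepdims=True)
    py = phenotype - phenotype.mean()
    return _slope_f(px, py, n - 2)


def m2_pvalues_arrays(values: np.ndarray, phenotype: np.ndarray, group: np.ndarray):
    """Group-adjusted slope F-test per gene row; returns (F, p), df = (1, n-3).

    Computed by Frisch-Waugh: phenotype and expression are residualized on
    [1, group] (within-group centering), then the simple slope is tested.
    Genes constant within each group are collinear with the group column and
    get NaN.
    """
    n = values.shape[1]
    if n < 4:
        raise ValueError("M2 needs at least 4 samples")
    px = values.copy().astype(float)
    py = phenotype.astype(float).copy()
    for g in (0, 1):
        m = group == g
        px[:, m] -= px[:, m].mean(axis=1, keepdims=True)
        py[m] -= py[m].mean()
    return _slope_f(px, py, n - 3)


def _as_results(expr: ExpressionMatrix, method: str, F, p) -> pd.DataFrame:
    return pd.DataFrame(
        {"gene_id": expr.gene_ids, "method": method, "statistic": F, "pvalue": p}
    )


def pag_m1(expr: ExpressionMatrix, design: StudyDesign) -> pd.DataFrame:
    check_aligned(expr, design)
    F, p = m1_pvalues_arrays(expr.values, design.phenotype)
    return _as_results(expr, "m1", F, p)


def pag_m2(expr: ExpressionMatrix, design: StudyDesign) -> pd.DataFrame:
    check_aligned(expr, design)
    F, p = m2_pvalues_arrays(expr.values, design.phenotype, design.group)
    return _as_results(expr, "m2", F, p)
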