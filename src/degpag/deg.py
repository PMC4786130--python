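"""Per-gene two-group differential-expression tests.

Two callers are provided: the pooled-variance two-sample t-test, and the SAM
statistic ``d_i = (mean_case - mean_control) / (s_i + s0)`` with a
variance-stabilizing fudge factor ``s0`` and permutation-based median-FDR
calling. ``s_i`` is the pooled two-sample standard error of the mean
difference; ``s0`` is chosen, when not supplied, as the percentile of the
``s_i`` distribution that minimizes the coefficient of variation of the
median absolute ``d`` across quantile bins of ``s_i``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, StudyDesign, check_aligned

__all__ = [
    "ttest_deg",
    "sam_statistic",
    "choose_fudge_factor",
    "sam_permutation_fdr",
    "SamResult",
    "pooled_t_arrays",
    "sam_d_arrays",
]


def _pooled(values: np.ndarray, group: np.ndarray):
    """Mean difference (case - control), pooled SEM and df, per gene row."""
    x1 = values[:, group == 1]
    x0 = values[:, group == 0]
    n1, n0 = x1.shape[1], x0.shape[1]
    if min(n1, n0) < 2:
        raise ValueError("each group needs at least 2 samples")
    diff = x1.mean(axis=1) - x0.mean(axis=1)
    sp2 = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n0 - 1) * x0.var(axis=1, ddof=1)) / (
        n1 + n0 - 2
    )
    sem = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    return diff, sem, n1 + n0 - 2


def pooled_t_arrays(values: np.ndarray, group: np.ndarray):
    """Two-sided pooled t-test per gene row; returns (t, p).

    Genes with zero pooled variance get NaN statistics; a zero mean
    difference with positive variance gives t = 0, p = 1.
    """
    diff, sem, df = _pooled(values, group)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / sem
    t = np.where(sem == 0.0, np.nan, t)
    p = np.where(np.isnan(t), np.nan, 2.0 * stats.t.sf(np.abs(t), df))
    return t, p


def sam_d_arrays(values: np.ndarray, group: np.ndarray, s0: float) -> np.ndarray:
    """SAM statistic per gene row for a fixed fudge factor."""
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    diff, sem, _ = _pooled(values, group)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / (sem + s0)
    return np.where((sem + s0) == 0.0, np.nan, d)


def ttest_deg(expr: ExpressionMatrix, design: StudyDesign) -> pd.DataFrame:
    """Pooled two-sample t-test per gene; columns gene_id/method/statistic/pvalue."""
    check_aligned(expr, design)
    t, p = pooled_t_arrays(expr.values, design.group)
    return pd.DataFrame(
        {"gene_id": expr.gene_ids, "method": "ttest", "statistic": t, "pvalue": p}
    )


def sam_statistic(
    expr: ExpressionMatrix, design: StudyDesign, s0: float
) -> np.ndarray:
    check_aligned(expr, design)
    return sam_d_arrays(expr.values, design.group, s0)


def choose_fudge_factor(
    expr: ExpressionMatrix, design: StudyDesign, n_bins: int | None = None
) -> float:
    """Pick s0 from the percentiles {0, 5, ..., 100} of the s_i distribution.

    The winning percentile minimizes the coefficient of variation of the
    median |d| across quantile bins of s_i, so that the magnitude of d is as
    independent of the gene-wise standard error as possible. Deterministic.
    """
    check_aligned(expr, design)
    if expr.n_genes < 10:
        raise ValueError("fudge-factor selection needs at least 10 genes")
    diff, sem, _ = _pooled(expr.values, design.group)
    if np.ptp(sem) == 0.0:
        warnings.warn("all gene-wise standard errors identical; s0 = common value")
        return float(sem[0])
    if n_bins is None:
        n_bins = int(min(100, max(2, expr.n_genes // 10)))
    # quantile bins of s_i, fixed across candidate percentiles
    bins = pd.qcut(sem, n_bins, labels=False, duplicates="drop")
    candidates = np.percentile(sem, np.arange(0, 101, 5))
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.abs(diff / (sem + s0))
        v = pd.Series(d).groupby(bins).median().to_numpy()
        v = v[np.isfinite(v)]
        mean_v = v.mean()
        cv = np.inf if mean_v == 0 else v.std(ddof=1) / mean_v
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return float(best_s0)


@dataclass
class SamResult:
    """SAM output: statistics, permutation expectations, and per-delta calls.

    ``table`` has one row per delta with n_called and the median permutation
    FDR; ``called`` maps each delta to the per-gene boolean call mask (in
    input gene order).
    """

    gene_ids: list[str]
    d: np.ndarray
    s: np.ndarray
    s0: float
    d_expected: np.ndarray
    table: pd.DataFrame
    called: dict
    n_permutations: int

    def called_at(self, delta: float) -> np.ndarray:
        return self.called[delta]


def _permutation_groups(n: int, n1: int, n_perm: int, seed: int):
    """All C(n, n1) case-assignments when feasible, else seeded draws."""
    total = comb(n, n1)
    if total <= n_perm:
        for combo in itertools.combinations(range(n), n1):
            g = np.zeros(n, dtype=int)
            g[list(combo)] = 1
            yield g
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            g = np.zeros(n, dtype=int)
            g[rng.choice(n, size=n1, replace=False)] = 1
            yield g


def sam_permutation_fdr(
    expr: ExpressionMatrix,
    design: StudyDesign,
    delta_grid,
    n_perm: int = 1000,
    seed: int = 0,
    s0: float | None = None,
) -> SamResult:
    """SAM calling with permutation-based median FDR.

    For each group-label permutation the full statistic (including the
    gene-wise standard error) is recomputed; ``d_expected`` is the mean of
    the order statistics of the permuted d values. A gene is called at a
    given delta when the displacement of its ordered d from d_expected is at
    least delta; the median FDR is the median permutation call count divided
    by the observed call count, capped at 1.
    """
    check_aligned(expr, design)
    delta_grid = list(delta_grid)
    if not delta_grid:
        raise ValueError("delta_grid must be non-empty")
    if any(dl < 0 for dl in delta_grid):
        raise ValueError("delta values must be non-negative")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if s0 is None:
        s0 = choose_fudge_factor(expr, design)

    values, group = expr.values, design.group
    n, n1 = len(group), int(group.sum())
    d_obs = sam_d_arrays(values, group, s0)
    _, sem, _ = _pooled(values, group)

    perm_sorted = np.array(
        [
            np.sort(sam_d_arrays(values, g, s0))
            for g in _permutation_groups(n, n1, n_perm, seed)
        ]
    )
    n_used = perm_sorted.shape[0]
    d_expected = perm_sorted.mean(axis=0)

    order = np.argsort(d_obs)
    disp_obs = np.abs(d_obs[order] - d_expected)
    disp_perm = np.abs(perm_sorted - d_expected)  # (n_perm, n_genes)

    rows, called = [], {}
    for delta in delta_grid:
        mask_sorted = disp_obs >= delta
        mask = np.zeros_like(mask_sorted)
        mask[order] = mask_sorted
        n_called = int(mask.sum())
        if n_called == 0:
            fdr = 0.0
        else:
            med = float(np.median((disp_perm >= delta).sum(axis=1)))
            fdr = min(1.0, med / n_called)
        rows.append({"delta": delta, "n_called": n_called, "median_fdr": fdr})
        called[delta] = mask
    return SamResult(
        gene_ids=expr.gene_ids,
        d=d_obs,
        s=sem,
        s0=float(s0),
        d_expected=d_expected,
        table=pd.DataFrame(rows),
        called=called,
        n_permutations=n_used,
    )
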