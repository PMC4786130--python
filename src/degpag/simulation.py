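"""Monte-Carlo type-I-error and power engine for the joint tests.

Each replicate draws one gene for a balanced two-group design from the
generative model

    expression = gamma0 + gamma1 * group + gamma2 * phenotype + eps

with phenotype ~ N(pheno_mean, pheno_var) independent of group and
eps ~ N(0, noise_var). Defaults mirror a serum-adiponectin phenotype
(mean 25.06, variance 274.896, assay units), 25 cases / 25 controls, and
expression noise variance 78.3. A rejection study sweeps a (gamma1, gamma2)
grid, applies each joint method at a fixed level per replicate, and records
the rejection fraction with its binomial Monte-Carlo standard error.

The naive and hierarchical methods use raw p-value thresholds at each
stage (the fixed-5%-per-test comparison); the model-based method is the
intersection-union LRT against chi-square(1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, StudyDesign
from .deg import pooled_t_arrays
from .joint import model_lrt_arrays
from .pag import m1_pvalues_arrays, m2_pvalues_arrays

__all__ = [
    "SimulationConfig",
    "METHODS",
    "simulate_dataset",
    "run_rejection_study",
    "plot_power_curves",
]

METHODS = ("naive_m1", "naive_m2", "hier_m1", "hier_m2", "model_based")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative and study parameters.

    gamma1 is the group effect in expression units; gamma2 the phenotype
    slope in expression units per phenotype unit.
    """

    n_case: int = 25
    n_control: int = 25
    pheno_mean: float = 25.06
    pheno_var: float = 274.896
    gamma0: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    noise_var: float = 78.3
    n_reps: int = 1000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if self.pheno_var <= 0 or self.noise_var <= 0:
            raise ValueError("variances must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def _draw_arrays(config: SimulationConfig, rep_index: int):
    """One replicate's (group, phenotype, expression) arrays.

    The RNG is keyed by (seed, rep_index), so every replicate is
    independently reproducible and the phenotype/noise draws are shared
    across effect-size cells run at the same seed (common random numbers).
    """
    rng = np.random.default_rng((config.seed, rep_index))
    n = config.n_control + config.n_case
    group = np.concatenate(
        [np.zeros(config.n_control, dtype=int), np.ones(config.n_case, dtype=int)]
    )
    phenotype = rng.normal(config.pheno_mean, np.sqrt(config.pheno_var), n)
    eps = rng.normal(0.0, np.sqrt(config.noise_var), n)
    expression = (
        config.gamma0 + config.gamma1 * group + config.gamma2 * phenotype + eps
    )
    return group, phenotype, expression


def simulate_dataset(config: SimulationConfig, rep_index: int):
    """One single-gene replicate as (ExpressionMatrix, StudyDesign)."""
    group, phenotype, expression = _draw_arrays(config, rep_index)
    n = group.size
    sample_ids = [f"s{i:03d}" for i in range(n)]
    expr = ExpressionMatrix(expression[None, :], ["g1"], sample_ids)
    design = StudyDesign(
        sample_ids=sample_ids,
        group=group,
        phenotype=phenotype,
        phenotype_name="phenotype",
    )
    return expr, design


def _rejections(config: SimulationConfig, methods) -> dict:
    """Per-method rejection counts over config.n_reps replicates."""
    alpha = config.alpha
    counts = dict.fromkeys(methods, 0)
    need_model = "model_based" in counts
    need_m2 = "naive_m2" in counts or "hier_m2" in counts
    need_m1 = "naive_m1" in counts or "hier_m1" in counts
    for rep in range(config.n_reps):
        group, phenotype, expression = _draw_arrays(config, rep)
        values = expression[None, :]
        _, p_t = pooled_t_arrays(values, group)
        deg_sig = p_t[0] < alpha
        if need_m1:
            _, p1 = m1_pvalues_arrays(values, phenotype)
            both = deg_sig and p1[0] < alpha
            for key in ("naive_m1", "hier_m1"):
                if key in counts:
                    counts[key] += both
        if need_m2:
            _, p2 = m2_pvalues_arrays(values, phenotype, group)
            both = deg_sig and p2[0] < alpha
            for key in ("naive_m2", "hier_m2"):
                if key in counts:
                    counts[key] += both
        if need_model:
            _, _, _, p_m3 = model_lrt_arrays(values, group, phenotype)
            counts["model_based"] += p_m3[0] < alpha
    return counts


def run_rejection_study(
    gamma1_grid,
    gamma2_grid,
    config: SimulationConfig | None = None,
    methods=METHODS,
) -> pd.DataFrame:
    """Rejection-rate table over the cross product of the two effect grids.

    Returns one row per (gamma1, gamma2, method) with columns
    rejection_rate, mc_se = sqrt(r(1-r)/n_reps), and n_reps. Deterministic
    for a fixed config.seed.
    """
    gamma1_grid, gamma2_grid = list(gamma1_grid), list(gamma2_grid)
    if not gamma1_grid or not gamma2_grid:
        raise ValueError("effect grids must be non-empty")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")
    if config is None:
        config = SimulationConfig()

    rows = []
    for g1, g2 in product(gamma1_grid, gamma2_grid):
        cfg = replace(config, gamma1=g1, gamma2=g2)
        counts = _rejections(cfg, methods)
        for method in methods:
            r = counts[method] / cfg.n_reps
            rows.append(
                {
                    "gamma1": g1,
                    "gamma2": g2,
                    "method": method,
                    "rejection_rate": r,
                    "mc_se": float(np.sqrt(r * (1.0 - r) / cfg.n_reps)),
                    "n_reps": cfg.n_reps,
                }
            )
    return pd.DataFrame(rows)


def plot_power_curves(
    table: pd.DataFrame, fixed: str = "gamma1", out_path="power_curves.png"
):
    """One panel per value of the fixed effect; rejection rate vs the other.

    Raises ValueError listing any (fixed value, method) series with missing
    grid cells. Returns the written file path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if fixed not in ("gamma1", "gamma2"):
        raise ValueError("fixed must be 'gamma1' or 'gamma2'")
    varying = "gamma2" if fixed == "gamma1" else "gamma1"
    fixed_vals = sorted(table[fixed].unique())
    var_vals = sorted(table[varying].unique())
    methods = list(dict.fromkeys(table["method"]))

    gaps = []
    for fv, m in product(fixed_vals, methods):
        sub = table[(table[fixed] == fv) & (table["method"] == m)]
        missing = set(var_vals) - set(sub[varying])
        if missing:
            gaps.append((fv, m, sorted(missing)))
    if gaps:
        raise ValueError(f"missing grid cells: {gaps}")

    ncol = min(3, len(fixed_vals))
    nrow = -(-len(fixed_vals) // ncol)
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False, sharey=True
    )
    greek = {"gamma1": r"$\gamma_1$", "gamma2": r"$\gamma_2$"}
    for ax, fv in zip(axes.flat, fixed_vals):
        for m in methods:
            sub = table[(table[fixed] == fv) & (table["method"] == m)].sort_values(
                varying
            )
            ax.plot(sub[varying], sub["rejection_rate"], marker="o", label=m)
        ax.set_title(f"{greek[fixed]} = {fv:g}")
        ax.set_xlabel(greek[varying])
        ax.set_ylabel("rejection rate")
    for ax in axes.flat[len(fixed_vals):]:
        ax.set_visible(False)
    axes.flat[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
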