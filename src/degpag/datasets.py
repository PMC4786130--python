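"""Synthetic multi-gene fixtures with named signal structures.

These generate small on-disk datasets for tests and tutorials. All kinds
share the simulation engine's generative model and defaults (balanced
25 + 25 design, phenotype ~ N(25.06, 274.896), expression noise variance
78.3); "planted" genes carry effects large enough to dominate the noise so
ranking checks are stable.

Kinds
-----
null
    Every gene has gamma1 = gamma2 = 0.
deg_only / pag_only / joint
    10% of genes (at least one) carry a strong group effect, phenotype
    slope, or both.
v1rh4_pattern
    The crossing geometry in which a group shift in both phenotype and
    expression cancels the marginal expression-phenotype slope: the
    marginal model (M1) misses the association, the group-adjusted model
    (M2) finds it. Constructed by zeroing the sample covariance between
    expression and phenotype exactly via the group column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data import ExpressionMatrix, StudyDesign

__all__ = ["FIXTURE_KINDS", "generate_fixture", "make_fixture"]

FIXTURE_KINDS = ("null", "deg_only", "pag_only", "joint", "v1rh4_pattern")

# strong planted effects (expression units; expression units per phenotype unit)
_GAMMA1_STRONG = 12.0
_GAMMA2_STRONG = 0.6


def generate_fixture(
    kind: str,
    n_genes: int = 100,
    seed: int = 0,
    n_case: int = 25,
    n_control: int = 25,
):
    """Build an in-memory fixture; returns (ExpressionMatrix, StudyDesign, planted).

    ``planted`` is the list of gene IDs carrying the named signal (empty for
    the null kind).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_control + n_case
    group = np.concatenate([np.zeros(n_control, dtype=int), np.ones(n_case, dtype=int)])
    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    sample_ids = [f"s{i:03d}" for i in range(n)]
    n_planted = max(1, n_genes // 10)
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)

    if kind == "v1rh4_pattern":
        # group-shifted phenotype so a group term can cancel the marginal slope
        phenotype = 25.06 + 15.0 * group + rng.normal(0.0, 5.0, n)
        values = rng.normal(0.0, np.sqrt(78.3), (n_genes, n))
        gdev = group - group.mean()
        pdev = phenotype - phenotype.mean()
        for i in planted_idx:
            base = phenotype + rng.normal(0.0, 1.0, n)  # within-group slope 1
            b = -float((base - base.mean()) @ pdev) / float(gdev @ pdev)
            values[i] = base + b * group
    else:
        phenotype = rng.normal(25.06, np.sqrt(274.896), n)
        gamma1 = np.zeros(n_genes)
        gamma2 = np.zeros(n_genes)
        if kind in ("deg_only", "joint"):
            gamma1[planted_idx] = _GAMMA1_STRONG
        if kind in ("pag_only", "joint"):
            gamma2[planted_idx] = _GAMMA2_STRONG
        eps = rng.normal(0.0, np.sqrt(78.3), (n_genes, n))
        values = gamma1[:, None] * group + gamma2[:, None] * phenotype + eps

    planted = [] if kind == "null" else [gene_ids[i] for i in sorted(planted_idx)]
    expr = ExpressionMatrix(values, gene_ids, sample_ids)
    design = StudyDesign(
        sample_ids=sample_ids,
        group=group,
        phenotype=phenotype,
        phenotype_name="phenotype",
    )
    return expr, design, planted


def make_fixture(
    kind: str, n_genes: int = 100, seed: int = 0, out_dir=".", **kwargs
):
    """Write a fixture to ``out_dir``; returns (expression_path, design_path)."""
    expr, design, _ = generate_fixture(kind, n_genes, seed, **kwargs)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expr_path = out_dir / f"{kind}_expression.tsv"
    design_path = out_dir / f"{kind}_design.tsv"
    expr.write(expr_path)
    import pandas as pd

    pd.DataFrame(
        {
            "sample_id": design.sample_ids,
            "group": design.group,
            design.phenotype_name: design.phenotype,
        }
    ).to_csv(design_path, sep="\t", index=False)
    return expr_path, design_path
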