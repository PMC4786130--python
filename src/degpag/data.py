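"""Core data containers and delimited-text I/O.

Expression matrices are genes-in-rows, samples-in-columns tables of
log-scale intensities; study designs carry a two-level group label and one
continuous phenotype per sample. Both are plain TSV/CSV with headers, as
exported by standard microarray pipelines. Input is assumed pre-normalized
(and optionally pre-logged) upstream; no background correction or quantile
normalization is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "StudyDesign",
    "DataFormatError",
    "AlignmentError",
    "read_expression",
    "read_design",
    "check_aligned",
    "write_results",
    "read_results",
]

#: group labels recognised as the control / reference level when coercing
#: arbitrary two-level labels to {0, 1}
CONTROL_LABELS = frozenset({"control", "ctrl", "nd", "normal", "wt", "untreated", "0"})

RESULT_COLUMNS = ["gene_id", "method", "statistic", "pvalue", "qvalue"]


class DataFormatError(ValueError):
    """Malformed input table (duplicate IDs, bad cells, bad group levels)."""


class AlignmentError(ValueError):
    """Expression matrix and study design disagree on the sample sequence."""


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes in rows and samples in columns.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Finite log-scale intensities.
    gene_ids, sample_ids : list of str
        Unique row and column labels, in file order.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise DataFormatError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataFormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene IDs x {len(self.sample_ids)} sample IDs"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise DataFormatError(f"duplicate {name} IDs present")
        if not np.all(np.isfinite(self.values)):
            raise DataFormatError("expression matrix contains non-finite values")
        if np.any(self.zero_variance):
            flagged = [g for g, z in zip(self.gene_ids, self.zero_variance) if z]
            warnings.warn(
                f"{len(flagged)} zero-variance gene(s) retained (will yield NaN "
                f"p-values): {flagged[:5]}{'...' if len(flagged) > 5 else ''}",
                stacklevel=2,
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def zero_variance(self) -> np.ndarray:
        """Boolean mask of genes constant across all samples."""
        return np.ptp(self.values, axis=1) == 0.0

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def write(self, path) -> None:
        """Write as TSV (first column gene IDs, header row sample IDs)."""
        self.to_dataframe().to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class StudyDesign:
    """Per-sample group membership and one continuous phenotype.

    ``group`` is coded 0 = control (e.g. normal diet), 1 = case (e.g. high
    fat diet); ``group_levels`` records the original-label mapping.
    """

    sample_ids: list[str]
    group: np.ndarray
    phenotype: np.ndarray
    phenotype_name: str = "phenotype"
    group_levels: dict = field(default_factory=lambda: {0: 0, 1: 1})

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.group = np.asarray(self.group, dtype=int)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise DataFormatError("duplicate sample IDs in design")
        if self.group.shape != (n,) or self.phenotype.shape != (n,):
            raise DataFormatError("group/phenotype length does not match sample IDs")
        levels, counts = np.unique(self.group, return_counts=True)
        if not np.array_equal(levels, [0, 1]):
            raise DataFormatError(
                f"exactly two group levels coded 0/1 required, got {levels.tolist()}"
            )
        if counts.min() < 2:
            raise DataFormatError("each group needs at least 2 samples")
        if not np.all(np.isfinite(self.phenotype)):
            raise DataFormatError("phenotype contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def read_expression(path, transform: str = "none") -> ExpressionMatrix:
    """Load a genes x samples expression table from delimited text.

    Parameters
    ----------
    path : path-like
        TSV/CSV file; first column gene IDs, header row sample IDs.
    transform : {"none", "log2"}
        With ``"log2"`` every raw value must be strictly positive and is
        replaced by its base-2 logarithm.
    """
    if transform not in ("none", "log2"):
        raise ValueError(f"unknown transform {transform!r}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise DataFormatError(f"duplicate gene or sample IDs in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"non-numeric cell at gene {df.index[gi]!r}, sample {df.columns[si]!r}"
        )
    if numeric.isna().to_numpy().any():
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataFormatError(
            f"missing value at gene {df.index[gi]!r}, sample {df.columns[si]!r}"
        )
    if transform == "log2":
        if (numeric.to_numpy() <= 0).any():
            raise DataFormatError("log2 transform requires strictly positive values")
        numeric = np.log2(numeric)
    return ExpressionMatrix.from_dataframe(numeric)


def read_design(path, phenotype_name: str | None = None) -> StudyDesign:
    """Load a study design from a table with columns sample_id, group, <phenotypes>.

    Group labels are coerced to {0, 1}: numeric 0/1 pass through; otherwise a
    recognised control label (ND, control, WT, ...) maps to 0, else the first
    label seen in the file maps to 0. ``phenotype_name`` defaults to the first
    phenotype column.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise DataFormatError(f"design file missing required column {col!r}")
    pheno_cols = [c for c in df.columns if c not in ("sample_id", "group")]
    if not pheno_cols:
        raise DataFormatError("design file has no phenotype column")
    if phenotype_name is None:
        phenotype_name = pheno_cols[0]
    if phenotype_name not in pheno_cols:
        raise KeyError(f"phenotype column {phenotype_name!r} not in {pheno_cols}")

    raw = df["group"]
    levels = list(dict.fromkeys(raw))
    if len(levels) != 2:
        raise DataFormatError(f"exactly 2 group levels required, got {levels}")
    if set(str(l) for l in levels) <= {"0", "1"}:
        mapping = {l: int(l) for l in levels}
    else:
        control = [l for l in levels if str(l).lower() in CONTROL_LABELS]
        zero = control[0] if control else levels[0]
        one = levels[1] if levels[0] == zero else levels[0]
        mapping = {zero: 0, one: 1}
    group = raw.map(mapping).to_numpy()
    return StudyDesign(
        sample_ids=list(df["sample_id"]),
        group=group,
        phenotype=pd.to_numeric(df[phenotype_name]).to_numpy(),
        phenotype_name=phenotype_name,
        group_levels={v: k for k, v in mapping.items()},
    )


def check_aligned(expr: ExpressionMatrix, design: StudyDesign) -> None:
    """Raise :class:`AlignmentError` unless sample ID sequences match exactly."""
    if expr.sample_ids != design.sample_ids:
        raise AlignmentError(
            "expression and design sample IDs differ "
            f"(expression starts {expr.sample_ids[:3]}, design {design.sample_ids[:3]})"
        )


def write_results(results: pd.DataFrame, path) -> None:
    """Write a per-gene result table as TSV with a deterministic column order."""
    out = results.copy()
    if "qvalue" not in out.columns:
        out["qvalue"] = np.nan
    if "statistic" not in out.columns and "lambda" in out.columns:
        out = out.rename(columns={"lambda": "statistic"})
    extra = [c for c in out.columns if c not in RESULT_COLUMNS]
    out[RESULT_COLUMNS + extra].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
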