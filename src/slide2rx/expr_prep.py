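"""Bulk expression preparation: expressed-gene filtering, normalization and
partitioning of genes into tranches of similar median expression.

Counts arrive as a genes x samples matrix of reads.  Expressed genes are
those with counts-per-million >= ``cpm_min`` in at least ``frac_samples`` of
samples (the usual edgeR-style rule).  Normalization is log2(1 + CPM); the
recipe string is carried on the output for provenance.  For the multi-task
regressors, genes are sorted by per-gene median normalized expression
(descending, ties broken lexicographically by identifier) and chunked into
consecutive tranches of ``tranche_size`` genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "GeneTranche",
    "filter_expressed_genes",
    "normalize_expression",
    "make_tranches",
]

DEFAULT_CPM_MIN = 1.0
DEFAULT_FRAC_SAMPLES = 0.2
DEFAULT_TRANCHE_SIZE = 4096


@dataclass
class CountMatrix:
    """Non-negative read counts, genes x samples."""

    counts: pd.DataFrame  # index = genes, columns = samples

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes x samples, finite values."""

    values: pd.DataFrame
    normalization_tag: str = "log2_1p_cpm"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path, normalization_tag: str = "unknown") -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0), normalization_tag)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass
class GeneTranche:
    tranche_index: int
    gene_ids: list[str]
    median_range: tuple[float, float] = (float("nan"), float("nan"))

    def __len__(self) -> int:
        return len(self.gene_ids)


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero) > 0:
        raise ValueError(f"all-zero library for sample(s): {list(zero.index)}")
    return counts / lib * 1e6


def filter_expressed_genes(
    counts: CountMatrix,
    cpm_min: float = DEFAULT_CPM_MIN,
    frac_samples: float = DEFAULT_FRAC_SAMPLES,
) -> list[str]:
    """Genes with CPM >= ``cpm_min`` in >= ``frac_samples`` of samples.

    Input gene order is preserved.  With ``cpm_min = 0`` the filter is
    vacuous and every gene is kept.
    """
    if counts.counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to filter expressed genes")
    if cpm_min <= 0:
        return counts.genes
    cpm = _cpm(counts.counts)
    keep = (cpm >= cpm_min).mean(axis=1) >= frac_samples
    return [g for g, k in zip(counts.genes, keep) if k]


def normalize_expression(counts: CountMatrix) -> ExpressionMatrix:
    """log2(1 + CPM) per sample; scale-invariant in library size."""
    cpm = _cpm(counts.counts)
    return ExpressionMatrix(np.log2(1.0 + cpm), normalization_tag="log2_1p_cpm")


def make_tranches(
    expr: ExpressionMatrix, tranche_size: int = DEFAULT_TRANCHE_SIZE
) -> list[GeneTranche]:
    """Partition genes into median-expression tranches.

    Genes are sorted by per-gene median expression across samples
    (descending; ties broken lexicographically by gene identifier) and cut
    into consecutive blocks of ``tranche_size``; the last block may be
    smaller.  The blocks partition the gene list and have non-overlapping
    median ranges by construction.
    """
    if tranche_size < 1:
        raise ValueError("tranche_size must be >= 1")
    if len(expr.genes) == 0:
        return []
    medians = expr.values.median(axis=1)
    order = sorted(expr.genes, key=lambda g: (-medians[g], g))
    tranches = []
    for i in range(0, len(order), tranche_size):
        block = order[i : i + tranche_size]
        med = medians[block]
        tranches.append(
            GeneTranche(
                tranche_index=i // tranche_size,
                gene_ids=list(block),
                median_range=(float(med.min()), float(med.max())),
            )
        )
    return tranches
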