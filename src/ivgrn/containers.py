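"""Typed containers for the matrices and tables the pipeline moves between stages.

The central objects are an expression matrix ``Y`` (samples x genes, log2
scale once preprocessed), a genotype dosage matrix ``X`` (samples x variants,
entries in {0, 1, 2} with missing allowed until imputation), and the inferred
network: a sparse signed coefficient matrix ``Gamma`` whose entry (i, j) is
the regulatory effect of gene j ON gene i, together with its binary adjacency
and, after bootstrapping, an edge-frequency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "GenotypeMatrix",
    "VariantInfo",
    "GeneAnnotation",
    "RegulatoryNetwork",
    "BootstrapSummary",
    "ThresholdedGraph",
]


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what} IDs: {sorted(set(dups))}")
    return ids


@dataclass
class ExpressionMatrix:
    """Samples x genes expression matrix with aligned id lists.

    ``values`` holds raw counts before preprocessing and log2-scale
    expression afterwards; missing cells are NaN and must be gone by the
    time inference runs.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def subset_genes(self, keep: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in keep]
        return ExpressionMatrix(self.values[:, idx].copy(), list(self.sample_ids), list(keep))

    def subset_samples(self, keep: list[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return ExpressionMatrix(self.values[idx, :].copy(), list(keep), list(self.gene_ids))

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.sample_ids), list(self.gene_ids))


@dataclass
class VariantInfo:
    """Metadata for one genotypic variant (1-based position)."""

    id: str
    chromosome: str
    position: int
    ref: str = "N"
    alt: str = "N"
    maf: float | None = None

    def __post_init__(self) -> None:
        self.position = int(self.position)
        if self.position < 1:
            raise ValueError(f"variant {self.id}: position must be >= 1")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"variant {self.id}: MAF {self.maf} outside [0, 0.5]")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix; dosage counts the alt allele.

    Entries are 0, 1, 2 or NaN (missing). ``variants`` carries one
    :class:`VariantInfo` per column, in column order.
    """

    dosages: np.ndarray
    variants: list[VariantInfo]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        _check_unique([v.id for v in self.variants], "variant")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosage values outside {{0,1,2,NA}}: {sorted(set(bad))[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def alt_frequency(self) -> np.ndarray:
        """Per-variant alt-allele frequency over non-missing samples."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def compute_maf(self) -> np.ndarray:
        """Compute and store per-variant minor allele frequencies."""
        af = self.alt_frequency()
        maf = np.minimum(af, 1.0 - af)
        for v, m in zip(self.variants, maf):
            v.maf = float(m) if np.isfinite(m) else None
        return maf

    def subset_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx].copy(),
            [self.variants[i] for i in idx],
            list(self.sample_ids),
        )

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[idx, :].copy(),
            list(self.variants),
            [self.sample_ids[i] for i in idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(),
            [VariantInfo(v.id, v.chromosome, v.position, v.ref, v.alt, v.maf) for v in self.variants],
            list(self.sample_ids),
        )


@dataclass
class GeneAnnotation:
    """Genomic location of one gene, 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


class RegulatoryNetwork:
    """Directed, signed gene-gene network.

    ``coefficients[i, j]`` is the estimated regulatory effect of gene j on
    gene i; the adjacency is the support of the coefficient matrix. The
    diagonal is structurally zero (no self-regulation in the model).
    """

    def __init__(self, coefficients, gene_ids: list[str]):
        coef = sp.csr_matrix(coefficients, dtype=float)
        if coef.shape[0] != coef.shape[1]:
            raise ValueError("coefficient matrix must be square")
        gene_ids = _check_unique(gene_ids, "gene")
        if coef.shape[0] != len(gene_ids):
            raise ValueError("coefficient matrix size does not match gene list")
        if coef.diagonal().any():
            raise ValueError("coefficient diagonal must be zero (no self-regulation)")
        coef.eliminate_zeros()
        self.coefficients = coef
        self.gene_ids = gene_ids

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def adjacency(self) -> sp.csr_matrix:
        adj = (self.coefficients != 0).astype(np.int8)
        return sp.csr_matrix(adj)

    @property
    def n_edges(self) -> int:
        return int(self.coefficients.nnz)

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges as (regulator, target, coefficient), sorted for determinism."""
        coo = self.coefficients.tocoo()
        rows = [
            (self.gene_ids[j], self.gene_ids[i], float(v))
            for i, j, v in zip(coo.row, coo.col, coo.data)
        ]
        return sorted(rows)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(r, t) for r, t, _ in self.edges()}

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self.gene_ids == other.gene_ids and self.edges() == other.edges()


class BootstrapSummary:
    """Componentwise edge frequencies over B bootstrap networks.

    Frequencies are stored as integer counts divided once by B, so every
    entry is an exact multiple of 1/B.
    """

    def __init__(self, counts, n_bootstraps: int, gene_ids: list[str]):
        counts = np.asarray(counts)
        if not np.issubdtype(counts.dtype, np.integer):
            raise TypeError("bootstrap counts must be integers")
        if counts.shape[0] != counts.shape[1]:
            raise ValueError("count matrix must be square")
        if n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")
        if counts.min() < 0 or counts.max() > n_bootstraps:
            raise ValueError("counts outside [0, B]")
        if np.diagonal(counts).any():
            raise ValueError("diagonal counts must be zero")
        gene_ids = _check_unique(gene_ids, "gene")
        if counts.shape[0] != len(gene_ids):
            raise ValueError("count matrix size does not match gene list")
        self.counts = counts.astype(np.int64)
        self.n_bootstraps = int(n_bootstraps)
        self.gene_ids = gene_ids

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def frequency(self) -> np.ndarray:
        return self.counts / self.n_bootstraps

    def edges(self) -> list[tuple[str, str, float]]:
        i_idx, j_idx = np.nonzero(self.counts)
        rows = [
            (self.gene_ids[j], self.gene_ids[i], self.counts[i, j] / self.n_bootstraps)
            for i, j in zip(i_idx, j_idx)
        ]
        return sorted(rows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BootstrapSummary):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.n_bootstraps == other.n_bootstraps
            and np.array_equal(self.counts, other.counts)
        )


class ThresholdedGraph:
    """Binary directed graph E_ij = 1[frequency(i, j) >= cutoff]."""

    def __init__(self, edges, cutoff: float, gene_ids: list[str]):
        E = np.asarray(edges)
        if E.shape[0] != E.shape[1]:
            raise ValueError("edge matrix must be square")
        if not np.isin(E, (0, 1)).all():
            raise ValueError("edge matrix entries must be 0/1")
        if np.diagonal(E).any():
            raise ValueError("edge matrix diagonal must be zero")
        if not (0.0 < cutoff <= 1.0):
            raise ValueError(f"cutoff {cutoff} outside (0, 1]")
        gene_ids = _check_unique(gene_ids, "gene")
        if E.shape[0] != len(gene_ids):
            raise ValueError("edge matrix size does not match gene list")
        self.edges = E.astype(np.int8)
        self.cutoff = float(cutoff)
        self.gene_ids = gene_ids

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(self.edges.sum())

    def edge_set(self) -> set[tuple[str, str]]:
        i_idx, j_idx = np.nonzero(self.edges)
        return {(self.gene_ids[j], self.gene_ids[i]) for i, j in zip(i_idx, j_idx)}
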