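"""Synthetic data with known ground truth from the structural model.

The generator draws Hardy-Weinberg genotypes X (dosage ~ Binomial(2,
MAF)), a sparse cyclic regulatory matrix Gamma with spectral radius kept
below 0.9 so I - Gamma stays well-conditioned, sparse cis effects Psi
respecting each gene's cis window, Gaussian disturbances, and solves the
structural system Y = Y Gamma' + X Psi + eps exactly. Gamma is stored
in the package-wide orientation (entry (i, j) is the effect of gene j on
gene i), so the closed-form solution is Y = (X Psi + eps)(I - Gamma)^{-T}.

Genes sit on one synthetic chromosome at fixed 10 kb spacing with their
cis variants inside the gene body, so window logic is exercised
literally. Expression is emitted on the log scale directly for
inference tests; a Poisson count mode exists solely to exercise the
preprocessing filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    ExpressionMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    RegulatoryNetwork,
    ThresholdedGraph,
    VariantInfo,
)

__all__ = [
    "SyntheticTruth",
    "RecoveryReport",
    "simulate_genotypes",
    "simulate_grn",
    "simulate_expression",
    "make_annotation",
    "simulate_dataset",
    "score_recovery",
    "counts_from_log_expression",
]

GENE_SPACING = 10_000
GENE_LENGTH = 5_000


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    Gamma: np.ndarray        # p x p, zero diagonal, spectral radius < 0.9
    Psi: np.ndarray          # q x p cis effects, support inside cis windows
    mafs: np.ndarray
    noise_sd: float
    seed: int

    def edge_set(self, gene_ids: list[str]) -> set[tuple[str, str]]:
        """True directed edges as (regulator, target) pairs.

        Gamma[i, j] is the effect of gene j on gene i.
        """
        i_idx, j_idx = np.nonzero(self.Gamma)
        return {(gene_ids[j], gene_ids[i]) for i, j in zip(i_idx, j_idx)}


@dataclass
class RecoveryReport:
    """Edge-recovery confusion counts against a known truth."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    sign_agreement: float | None
    precision_defined: bool


def simulate_genotypes(n: int, variant_specs: list[tuple[str, int, float]],
                       seed: int = 0, missing_rate: float = 0.0) -> GenotypeMatrix:
    """HWE dosages: Binomial(2, maf) per variant; optional injected missingness."""
    rng = np.random.default_rng(seed)
    mafs = np.array([m for _, _, m in variant_specs])
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise ValueError("MAFs must lie in (0, 0.5]")
    dosages = rng.binomial(2, mafs, size=(n, len(variant_specs))).astype(float)
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = np.nan
    variants = [
        VariantInfo(f"snp{j}", chrom, pos, "A", "G")
        for j, (chrom, pos, _) in enumerate(variant_specs)
    ]
    return GenotypeMatrix(dosages, variants, [f"s{i}" for i in range(n)])


def simulate_grn(p: int, n_edges: int, effect_range: tuple[float, float] = (0.4, 0.6),
                 allow_cycles: bool = True, seed: int = 0,
                 planted_cycle: list[int] | None = None,
                 max_spectral_radius: float = 0.9,
                 max_tries: int = 200) -> np.ndarray:
    """Random sparse Gamma with |effects| in ``effect_range`` and spectral
    radius < 0.9 (rejection-resampled)."""
    if n_edges > p * (p - 1):
        raise ValueError("too many edges requested")
    rng = np.random.default_rng(seed)
    lo, hi = effect_range
    for _ in range(max_tries):
        Gamma = np.zeros((p, p))
        if planted_cycle:
            cyc = list(planted_cycle)
            for a, b in zip(cyc, cyc[1:] + cyc[:1]):
                # b regulates a's successor: edge a -> b means Gamma[b, a] != 0
                Gamma[b, a] = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        pairs = [(i, j) for i in range(p) for j in range(p) if i != j and Gamma[i, j] == 0]
        need = n_edges - int(np.count_nonzero(Gamma))
        if need > 0:
            chosen = rng.choice(len(pairs), size=need, replace=False)
            for c in chosen:
                i, j = pairs[c]
                if not allow_cycles and _would_cycle(Gamma, i, j):
                    continue
                Gamma[i, j] = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        if np.max(np.abs(np.linalg.eigvals(Gamma))) < max_spectral_radius:
            return Gamma
    raise RuntimeError("could not draw a stable Gamma within the retry budget")


def _would_cycle(Gamma: np.ndarray, i: int, j: int) -> bool:
    """True if adding effect of j on i (edge j -> i) closes a directed cycle."""
    # reachability from i to j along existing edges regulator -> target
    p = Gamma.shape[0]
    adj = (Gamma != 0)
    seen = {i}
    stack = [i]
    while stack:
        t = stack.pop()
        for nxt in range(p):
            if adj[nxt, t] and nxt not in seen:  # t regulates nxt
                if nxt == j:
                    return True
                seen.add(nxt)
                stack.append(nxt)
    return False


def simulate_expression(X: GenotypeMatrix | np.ndarray, Psi: np.ndarray,
                        Gamma: np.ndarray, noise_sd: float = 1.0,
                        seed: int = 0,
                        gene_ids: list[str] | None = None,
                        return_noise: bool = False):
    """Solve the structural system exactly with Gaussian eps.

    Gamma follows the package-wide orientation (entry (i, j) = effect of
    gene j on gene i), so the system reads Y = Y Gamma' + X Psi + eps and
    its exact solution is Y = (X Psi + eps)(I - Gamma)^{-T}.
    """
    dosages = X.dosages if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
    p = Gamma.shape[0]
    I_minus = np.eye(p) - Gamma
    if abs(np.linalg.det(I_minus)) < 1e-12:
        raise ValueError("I - Gamma is singular; system has no stable solution")
    rng = np.random.default_rng(seed)
    n = dosages.shape[0]
    eps = rng.normal(0.0, noise_sd, size=(n, p))
    Y = np.linalg.solve(I_minus, (dosages @ Psi + eps).T).T
    gene_ids = gene_ids or [f"g{k}" for k in range(p)]
    sample_ids = (X.sample_ids if isinstance(X, GenotypeMatrix)
                  else [f"s{i}" for i in range(n)])
    expr = ExpressionMatrix(Y, list(sample_ids), gene_ids)
    return (expr, eps) if return_noise else expr


def make_annotation(p: int, chrom: str = "chr1") -> list[GeneAnnotation]:
    """Genes at fixed 10 kb spacing on one chromosome, 5 kb bodies."""
    return [
        GeneAnnotation(f"g{k}", chrom, 1 + k * GENE_SPACING, k * GENE_SPACING + GENE_LENGTH)
        for k in range(p)
    ]


def counts_from_log_expression(expr: ExpressionMatrix, seed: int = 0) -> ExpressionMatrix:
    """Poisson counts around 2^Y, for exercising count-scale preprocessing."""
    rng = np.random.default_rng(seed)
    lam = np.clip(2.0 ** expr.values, 0, 1e9)
    counts = rng.poisson(lam).astype(float)
    return ExpressionMatrix(counts, list(expr.sample_ids), list(expr.gene_ids))


def simulate_dataset(p: int = 30, n: int = 800, cis_per_gene: int = 2,
                     maf: float = 0.3, cis_effect: float = 0.8,
                     n_edges: int = 10, effect_range: tuple[float, float] = (0.5, 0.5),
                     noise_sd: float = 1.0, seed: int = 0,
                     allow_cycles: bool = True,
                     planted_cycle: list[int] | None = None,
                     ):
    """One complete dataset: genotypes, annotation, expression, truth.

    Each gene gets ``cis_per_gene`` variants inside its gene body with
    cis effect ``cis_effect`` on its own expression; ``n_edges`` random
    regulations with |effect| drawn from ``effect_range``.
    Returns (expression, genotypes, annotation, truth).
    """
    ann = make_annotation(p)
    specs = []
    for k, gene in enumerate(ann):
        for c in range(cis_per_gene):
            pos = gene.start + 100 + c * 400
            specs.append((gene.chromosome, pos, maf))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    X = simulate_genotypes(n, specs, seed=int(rng.integers(2 ** 31)))
    q = len(specs)
    Psi = np.zeros((q, p))
    for k in range(p):
        for c in range(cis_per_gene):
            Psi[k * cis_per_gene + c, k] = cis_effect
    Gamma = simulate_grn(p, n_edges, effect_range, allow_cycles,
                         seed=int(rng.integers(2 ** 31)), planted_cycle=planted_cycle)
    expr = simulate_expression(X, Psi, Gamma, noise_sd,
                               seed=int(rng.integers(2 ** 31)),
                               gene_ids=[g.gene_id for g in ann])
    truth = SyntheticTruth(Gamma, Psi, np.full(q, maf), noise_sd, seed)
    return expr, X, ann, truth


def score_recovery(truth: SyntheticTruth, estimate: RegulatoryNetwork | ThresholdedGraph,
                   gene_ids: list[str] | None = None) -> RecoveryReport:
    """Directed edge-recovery confusion counts, precision/recall/F1, and
    sign agreement on true positives (None when signs are unavailable).

    Orientation is respected: a true j -> i edge matches only an
    estimated j -> i edge. An empty estimate reports precision 1.0 with
    ``precision_defined=False``.
    """
    if gene_ids is None:
        gene_ids = list(estimate.gene_ids)
    if len(gene_ids) != truth.Gamma.shape[0]:
        raise ValueError("gene set mismatch between truth and estimate")
    if list(estimate.gene_ids) != list(gene_ids):
        raise ValueError("gene set mismatch between truth and estimate")
    true_edges = truth.edge_set(gene_ids)
    est_edges = estimate.edge_set()
    tp_edges = true_edges & est_edges
    tp, fp, fn = len(tp_edges), len(est_edges - true_edges), len(true_edges - est_edges)
    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0

    sign_agreement = None
    if isinstance(estimate, RegulatoryNetwork) and tp_edges:
        idx = {g: k for k, g in enumerate(gene_ids)}
        agree = 0
        coef = estimate.coefficients
        for reg, tgt in tp_edges:
            i, j = idx[tgt], idx[reg]
            if np.sign(coef[i, j]) == np.sign(truth.Gamma[i, j]):
                agree += 1
        sign_agreement = agree / len(tp_edges)
    return RecoveryReport(tp, fp, fn, precision, recall, f1, sign_agreement,
                          precision_defined)
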