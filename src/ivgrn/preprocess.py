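"""Expression and genotype preprocessing.

Expression: study-specific low-count gene filters, TMM (trimmed mean of
M-values) between-sample normalization, and a log2-CPM transform.
Genotypes: missing-rate filters, a Hardy-Weinberg equilibrium filter
(1-df chi-square by default, exact test optionally), minor-allele-count
filter, and major-allele fallback imputation.
Confounding: linear residualization of expression on covariates and on
top genotype principal components.

Two expression versions flow out of this module: the PC-adjusted one used
for instrument discovery, and the non-PC-adjusted one used for network
inference (population-structure PCs are confounders for local association
but carry global regulatory signal).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "filter_genes_gtex",
    "filter_genes_tcga",
    "tmm_normalize",
    "median_of_ratios_factors",
    "log2_transform",
    "hwe_chisq_pvalue",
    "hwe_exact_pvalue",
    "qc_genotypes",
    "GenotypeQC",
    "impute_major_allele",
    "genotype_pcs",
    "residualize",
    "Residualizer",
]


@dataclass
class QCReport:
    """Per-axis removal log: (id, reason) pairs plus per-filter counts."""

    genes_removed: list[tuple[str, str]] = field(default_factory=list)
    variants_removed: list[tuple[str, str]] = field(default_factory=list)
    samples_removed: list[tuple[str, str]] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    def add(self, axis: str, ids, reason: str) -> None:
        ids = list(ids)
        getattr(self, f"{axis}_removed").extend((str(i), reason) for i in ids)
        self.counts[reason] = self.counts.get(reason, 0) + len(ids)

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("gene", i, r) for i, r in self.genes_removed]
            + [("variant", i, r) for i, r in self.variants_removed]
            + [("sample", i, r) for i, r in self.samples_removed]
        )
        return pd.DataFrame(rows, columns=["axis", "id", "reason"])


# ---------------------------------------------------------------------------
# expression gene filters
# ---------------------------------------------------------------------------

def filter_genes_gtex(
    counts: ExpressionMatrix,
    tpm: ExpressionMatrix,
    tpm_threshold: float = 0.1,
    count_threshold: float = 6.0,
    min_fraction: float = 0.20,
) -> tuple[list[str], QCReport]:
    """Keep genes expressed at TPM > 0.1 in >= 20% of samples AND with
    >= 6 reads in >= 20% of samples (both fractions inclusive)."""
    if counts.gene_ids != tpm.gene_ids or counts.sample_ids != tpm.sample_ids:
        raise ValueError("counts and TPM matrices must share gene and sample IDs")
    n = counts.n_samples
    frac_tpm = (tpm.values > tpm_threshold).sum(axis=0) / n
    frac_reads = (counts.values >= count_threshold).sum(axis=0) / n
    keep = (frac_tpm >= min_fraction) & (frac_reads >= min_fraction)
    report = QCReport()
    report.add("genes", [g for g, k in zip(counts.gene_ids, keep) if not k], "low_expression_gtex")
    report.counts["genes_retained"] = int(keep.sum())
    return [g for g, k in zip(counts.gene_ids, keep) if k], report


def filter_genes_tcga(
    counts: ExpressionMatrix,
    min_total: float = 2_500_000.0,
    max_missing_fraction: float = 0.80,
) -> tuple[list[str], QCReport]:
    """Remove genes with total counts < 2.5 million (strict) or zero/missing
    in more than 80% of samples.

    Count matrices have no explicit NA, so zeros stand in for missingness.
    The total-count threshold is implausibly large for most genes; it is
    applied verbatim but exposed for override.
    """
    vals = counts.values
    total = np.nansum(vals, axis=0)
    missing_frac = (np.isnan(vals) | (vals == 0)).sum(axis=0) / counts.n_samples
    remove = (total < min_total) | (missing_frac > max_missing_fraction)
    report = QCReport()
    report.add("genes", [g for g, r in zip(counts.gene_ids, remove) if r], "low_expression_tcga")
    report.counts["genes_retained"] = int((~remove).sum())
    return [g for g, r in zip(counts.gene_ids, remove) if not r], report


# ---------------------------------------------------------------------------
# TMM normalization (Robinson-Oshlack)
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, sum_trim: float) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference.

    M and A are computed on library-size-normalized counts over genes
    positive in both libraries; M is trimmed 30% from each tail and A 5%
    from each tail by default; the mean is inverse-variance weighted
    (binomial delta-method weights).
    """
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 1.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    # binomial delta-method variance of M; precision weight is its inverse
    var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    w = 1.0 / var
    if np.allclose(M, 0.0, atol=1e-10):
        return 1.0
    n = M.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(M, method="average")
    rank_a = stats.rankdata(A, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(w[keep] * M[keep]) / np.sum(w[keep])
    return float(2.0 ** f)


def tmm_normalize(
    counts: ExpressionMatrix,
    reference: str | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> np.ndarray:
    """TMM scaling factors, one per sample, rescaled to log-mean zero.

    ``reference`` picks the reference sample by ID; by default the sample
    whose upper-quartile count fraction is closest to the across-sample
    mean is used. Factors multiply library sizes downstream (effective
    library size = library size x factor).
    """
    vals = counts.values
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    if np.isnan(vals).any():
        raise ValueError("TMM requires a complete count matrix")
    if (vals < 0).any():
        raise ValueError("TMM requires nonnegative counts")
    lib = vals.sum(axis=1)
    if (lib == 0).any():
        dead = [s for s, l in zip(counts.sample_ids, lib) if l == 0]
        raise ValueError(f"sample(s) with all-zero counts: {dead}")
    if reference is None:
        f75 = np.array([np.quantile(vals[i] / lib[i], 0.75) for i in range(len(lib))])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        try:
            ref_idx = counts.sample_ids.index(reference)
        except ValueError:
            raise KeyError(f"unknown reference sample {reference!r}") from None
    factors = np.array(
        [
            _tmm_pair(vals[i], vals[ref_idx], lib[i], lib[ref_idx], logratio_trim, sum_trim)
            for i in range(counts.n_samples)
        ]
    )
    # normalize so factors multiply to 1 (log-mean zero), as edgeR does
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def median_of_ratios_factors(counts: ExpressionMatrix) -> np.ndarray:
    """Median-of-ratios size factors (the DESeq convention), rescaled to
    log-mean zero and divided by relative library size so they slot into
    the same effective-library-size convention as TMM factors.

    This is the count-scale normalization used in TCGA mode in place of a
    variance-stabilizing transform; see the methods note.
    """
    vals = counts.values
    lib = vals.sum(axis=1)
    if (lib == 0).any():
        raise ValueError("sample with all-zero counts")
    with np.errstate(divide="ignore"):
        log_vals = np.log(vals)
    log_geo = log_vals.mean(axis=0)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no gene expressed in every sample; cannot form size factors")
    size = np.exp(np.median(log_vals[:, usable] - log_geo[usable], axis=1))
    factors = size / (lib / np.exp(np.mean(np.log(lib))))
    return factors / np.exp(np.mean(np.log(factors)))


def log2_transform(counts: ExpressionMatrix, factors: np.ndarray | None = None) -> ExpressionMatrix:
    """log2(CPM + 1) using effective library sizes (library size x factor)."""
    vals = counts.values
    lib = vals.sum(axis=1)
    if factors is None:
        factors = np.ones(counts.n_samples)
    factors = np.asarray(factors, dtype=float)
    if (factors <= 0).any():
        raise ValueError("scaling factors must be positive")
    eff = lib * factors
    out = np.log2(vals / eff[:, None] * 1e6 + 1.0)
    return ExpressionMatrix(out, list(counts.sample_ids), list(counts.gene_ids))


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium tests
# ---------------------------------------------------------------------------

def hwe_chisq_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """1-df chi-square goodness-of-fit p-value against HWE proportions."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p = (2 * n_hom_ref + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    stat = np.sum((obs - exp) ** 2 / exp)
    return float(stats.chi2.sf(stat, df=1))


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE test p-value (sum of probabilities of heterozygote counts
    no more likely than the observed one, conditional on allele counts)."""
    n_het, n_hom_ref, n_hom_alt = int(n_het), int(n_hom_ref), int(n_hom_alt)
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0 or rare == 0:
        return 1.0
    # probabilities over all het counts with the same parity as `rare`
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    het = mid
    while het > 1:
        nxt = het - 2
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        probs[nxt] = probs[het] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het = nxt
    het = mid
    while het <= rare - 2:
        nxt = het + 2
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        probs[nxt] = probs[het] * 4.0 * hom_r * hom_c / ((het + 2) * (het + 1))
        het = nxt
    total = sum(probs.values())
    obs_het = n_het
    p_obs = probs.get(obs_het, 0.0)
    pval = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total
    return float(min(pval, 1.0))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    ok = np.isfinite(col)
    c = col[ok]
    return int((c == 0).sum()), int((c == 1).sum()), int((c == 2).sum())


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

class GenotypeQC(BaseEstimator):
    """Genotype quality control as a fit-style filter.

    Applies, in order: variant missing-rate filter, sample missing-rate
    filter, Hardy-Weinberg filter, minor-allele-count filter; then
    computes per-variant MAF on the retained samples.

    Parameters
    ----------
    max_variant_missing, max_sample_missing : float
        Maximum tolerated missing fractions (default 0.10 each).
    hwe_alpha : float
        HWE rejection level (default 1e-4).
    min_mac : int
        Minimum minor allele count (default 5); variants strictly below
        are removed.
    hwe_test : {"chisq", "exact"}
        1-df chi-square goodness of fit (default) or the exact test.
    """

    def __init__(self, max_variant_missing: float = 0.10, max_sample_missing: float = 0.10,
                 hwe_alpha: float = 1e-4, min_mac: int = 5, hwe_test: str = "chisq"):
        self.max_variant_missing = max_variant_missing
        self.max_sample_missing = max_sample_missing
        self.hwe_alpha = hwe_alpha
        self.min_mac = min_mac
        self.hwe_test = hwe_test

    def fit(self, g: GenotypeMatrix, y=None) -> "GenotypeQC":
        if self.hwe_test not in ("chisq", "exact"):
            raise ValueError(f"unknown hwe_test {self.hwe_test!r}")
        hwe_fn = hwe_chisq_pvalue if self.hwe_test == "chisq" else hwe_exact_pvalue
        report = QCReport()

        miss_v = np.isnan(g.dosages).mean(axis=0)
        keep_v = miss_v <= self.max_variant_missing
        report.add("variants", [v.id for v, k in zip(g.variants, keep_v) if not k],
                   "variant_missing_rate")
        g = g.subset_variants(np.nonzero(keep_v)[0])

        if g.n_variants == 0:
            raise ValueError("no variants survive QC")

        miss_s = np.isnan(g.dosages).mean(axis=1)
        keep_s = miss_s <= self.max_sample_missing
        report.add("samples", [s for s, k in zip(g.sample_ids, keep_s) if not k],
                   "sample_missing_rate")
        g = g.subset_samples(np.nonzero(keep_s)[0])

        pvals = np.array([hwe_fn(*_genotype_counts(g.dosages[:, j]))
                          for j in range(g.n_variants)])
        keep_v = pvals >= self.hwe_alpha
        report.add("variants", [v.id for v, k in zip(g.variants, keep_v) if not k],
                   "hwe_violation")
        g = g.subset_variants(np.nonzero(keep_v)[0])

        with np.errstate(invalid="ignore"):
            alt = np.nansum(g.dosages, axis=0)
            n_called = np.isfinite(g.dosages).sum(axis=0)
        mac = np.minimum(alt, 2 * n_called - alt)
        keep_v = mac >= self.min_mac
        report.add("variants", [v.id for v, k in zip(g.variants, keep_v) if not k],
                   "minor_allele_count")
        g = g.subset_variants(np.nonzero(keep_v)[0])
        if g.n_variants == 0:
            raise ValueError("no variants survive QC")

        g.compute_maf()
        report.counts["variants_retained"] = g.n_variants
        report.counts["samples_retained"] = g.n_samples
        self.genotypes_ = g
        self.report_ = report
        self.hwe_pvalues_ = pvals
        return self


def qc_genotypes(g: GenotypeMatrix, max_var_missing: float = 0.10,
                 max_sample_missing: float = 0.10, hwe_alpha: float = 1e-4,
                 min_mac: int = 5, hwe_test: str = "chisq") -> tuple[GenotypeMatrix, QCReport]:
    qc = GenotypeQC(max_var_missing, max_sample_missing, hwe_alpha, min_mac, hwe_test).fit(g)
    return qc.genotypes_, qc.report_


def impute_major_allele(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the homozygous-major dosage.

    The major allele is ref when the alt frequency is <= 0.5 (missing
    becomes 0) and alt when the alt frequency exceeds 0.5 (missing
    becomes 2).
    """
    out = g.copy()
    af = out.alt_frequency()
    for j in range(out.n_variants):
        col = out.dosages[:, j]
        miss = ~np.isfinite(col)
        if miss.any():
            col[miss] = 2.0 if af[j] > 0.5 else 0.0
    return out


def genotype_pcs(g: GenotypeMatrix, k: int = 3) -> np.ndarray:
    """Top-k principal component scores of the column-standardized dosages.

    Zero-variance variants are dropped before standardization; the sign
    convention is deterministic (largest absolute loading positive).
    """
    if k == 0:
        return np.empty((g.n_samples, 0))
    if k >= g.n_samples:
        raise ValueError(f"k={k} must be < n_samples={g.n_samples}")
    X = g.dosages
    if np.isnan(X).any():
        raise ValueError("genotype PCs require imputed (complete) dosages")
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    if X.shape[1] == 0:
        raise ValueError("all variants have zero variance")
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    k = min(k, min(Z.shape) - 1) or 1
    pca = PCA(n_components=k, svd_solver="full")
    return pca.fit_transform(Z)


# ---------------------------------------------------------------------------
# confounder residualization
# ---------------------------------------------------------------------------

def _design_matrix(sample_ids: list[str], covariates: pd.DataFrame | None,
                   pcs: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(len(sample_ids))]
    if covariates is not None:
        cov = covariates.loc[sample_ids]
        for name in cov.columns:
            series = cov[name]
            if series.dtype.kind in "OUSb" or isinstance(series.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(series.astype(str), drop_first=True)
                for dcol in dummies.columns:
                    cols.append(dummies[dcol].to_numpy(dtype=float))
            else:
                cols.append(series.to_numpy(dtype=float))
    if pcs is not None and pcs.size:
        for j in range(pcs.shape[1]):
            cols.append(np.asarray(pcs[:, j], dtype=float))
    return np.column_stack(cols)


def _drop_collinear(D: np.ndarray) -> np.ndarray:
    """Greedy rank-revealing column drop (keeps the earliest spanning set)."""
    keep: list[int] = []
    for j in range(D.shape[1]):
        trial = D[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
    if len(keep) < D.shape[1]:
        logger.warning("dropped %d collinear design column(s)", D.shape[1] - len(keep))
    return D[:, keep]


class Residualizer(BaseEstimator):
    """Remove linear covariate (and genotype-PC) effects from expression.

    ``fit`` builds the design (intercept + dummy-coded categoricals +
    numeric covariates + PCs), dropping collinear columns; ``transform``
    replaces each gene's expression with its least-squares residual, so
    residuals are orthogonal to every design column. Residualizing twice
    is a no-op.
    """

    def __init__(self, covariates: pd.DataFrame | None = None, pcs: np.ndarray | None = None):
        self.covariates = covariates
        self.pcs = pcs

    def fit(self, expr: ExpressionMatrix, y=None) -> "Residualizer":
        D = _design_matrix(expr.sample_ids, self.covariates, self.pcs)
        self.design_ = _drop_collinear(D)
        self.q_, _ = np.linalg.qr(self.design_)
        return self

    def transform(self, expr: ExpressionMatrix) -> ExpressionMatrix:
        Y = expr.values
        resid = Y - self.q_ @ (self.q_.T @ Y)
        return ExpressionMatrix(resid, list(expr.sample_ids), list(expr.gene_ids))

    def fit_transform(self, expr: ExpressionMatrix, y=None) -> ExpressionMatrix:
        return self.fit(expr).transform(expr)


def residualize(expr: ExpressionMatrix, covariates: pd.DataFrame | None = None,
                pcs: np.ndarray | None = None) -> ExpressionMatrix:
    return Residualizer(covariates, pcs).fit_transform(expr)
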