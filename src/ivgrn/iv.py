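"""Cis genotypic instrument discovery.

For each gene, candidate instruments are sought inside its cis window
(gene body plus a 1 kb flank by default). Common variants (MAF >= 0.05)
are tested marginally by simple linear regression. Low-MAF (0.01 <= MAF
< 0.05) and rare (MAF < 0.01) variants are aggregated per class by the
adaptive-sum burden procedure: variants whose marginal effect is negative
and nominally significant are recoded (2 - dosage) before summing, and
significance of the resulting burden score is assessed by permutation
with the adaptive recoding recomputed inside every permutation, which
preserves the selection's null distribution.

Candidates significant at the per-gene level are then greedily selected
in ascending p-value order, admitting a candidate only while its absolute
correlation with every already-admitted instrument stays below 0.3, up to
three instruments per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import GeneAnnotation, GenotypeMatrix, ExpressionMatrix

__all__ = [
    "MAF_COMMON",
    "MAF_LOW",
    "cis_window",
    "classify_maf",
    "marginal_test",
    "asum_test",
    "select_ivs",
    "Instrument",
    "IVSet",
    "IVSelector",
]

MAF_COMMON = 0.05
MAF_LOW = 0.01


def cis_window(gene: GeneAnnotation, flank: int = 1000) -> tuple[str, int, int]:
    """Genomic interval [start - flank, end + flank], clipped at 1."""
    return gene.chromosome, max(1, gene.start - flank), gene.end + flank


def classify_maf(maf: float) -> str:
    """'common' (MAF >= 0.05), 'low' (0.01 <= MAF < 0.05) or 'rare' (< 0.01)."""
    if not (0.0 <= maf <= 0.5):
        raise ValueError(f"MAF {maf} outside [0, 0.5]")
    if maf >= MAF_COMMON:
        return "common"
    if maf >= MAF_LOW:
        return "low"
    return "rare"


def marginal_test(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Simple-regression slope of y on x and its two-sided t-test p-value.

    A zero-variance x is degenerate: returns (0.0, 1.0).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x must have equal length")
    n = y.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    if sxx == 0:
        return 0.0, 1.0
    slope = (xc @ yc) / sxx
    syy = yc @ yc
    if syy == 0:
        return float(slope), 1.0
    r2 = (xc @ yc) ** 2 / (sxx * syy)
    if n <= 2:
        return float(slope), 1.0
    if r2 >= 1.0:
        return float(slope), 0.0
    t = np.sqrt(r2 * (n - 2) / (1.0 - r2))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    return float(slope), float(p)


def _adaptive_burden_stats(C: np.ndarray, col_ss: np.ndarray, v: np.ndarray,
                           K: np.ndarray, s_ss: float, y_ss: float,
                           r_crit: float) -> np.ndarray:
    """Squared burden-score correlations for a block of (permuted) responses.

    ``C`` is the m x P matrix of centered cross-products g_j' y_p; the flip
    set of each column is {j : r_jp < -r_crit}; the burden statistic is the
    squared correlation between the recoded row-sum and the response.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        R = C / np.sqrt(np.outer(col_ss, np.full(C.shape[1], y_ss)))
    R[~np.isfinite(R)] = 0.0
    F = (R < -r_crit).astype(float)
    num = C.sum(axis=0) - 2.0 * (F * C).sum(axis=0)
    denom = s_ss - 4.0 * (F * v[:, None]).sum(axis=0) + 4.0 * ((K @ F) * F).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = num ** 2 / (denom * y_ss)
    stat[~np.isfinite(stat)] = 0.0
    stat[denom <= 1e-12] = 0.0
    return stat


def asum_test(y: np.ndarray, G: np.ndarray, alpha0: float = 0.1,
              n_perm: int = 1000, seed: int | None = None,
              rng: np.random.Generator | None = None) -> tuple[np.ndarray, float]:
    """Adaptive-sum burden test of y on a block of low-frequency variants.

    Returns the burden pseudo-variant built on the unpermuted data (row
    sum of the adaptively recoded dosage matrix) and the permutation
    p-value of its score statistic, with the flip-and-sum recomputed
    inside each permutation.
    """
    y = np.asarray(y, dtype=float)
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.shape[0] != y.size:
        raise ValueError("G rows must match length of y")
    if G.shape[1] < 1:
        raise ValueError("need at least one variant column")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    n, m = G.shape

    Gc = G - G.mean(axis=0)
    col_ss = (Gc ** 2).sum(axis=0)
    s = G.sum(axis=1)
    sc = s - s.mean()
    s_ss = float(sc @ sc)
    v = Gc.T @ sc
    K = Gc.T @ Gc
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    if y_ss == 0 or not np.any(col_ss > 0):
        return s.copy(), 1.0

    # flip rule "slope < 0 and marginal p < alpha0" as a correlation bound
    t_crit = stats.t.ppf(1.0 - alpha0 / 2.0, df=max(n - 2, 1))
    r_crit = t_crit / np.sqrt(n - 2 + t_crit ** 2)

    C_obs = Gc.T @ yc
    obs = _adaptive_burden_stats(C_obs[:, None], col_ss, v, K, s_ss, y_ss, r_crit)[0]

    # observed burden vector (adaptive recoding on unpermuted data)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_obs = C_obs / np.sqrt(col_ss * y_ss)
    r_obs[~np.isfinite(r_obs)] = 0.0
    flip = r_obs < -r_crit
    recoded = G.copy()
    recoded[:, flip] = 2.0 - recoded[:, flip]
    burden = recoded.sum(axis=1)

    # permutations in vectorized blocks
    exceed = 0
    block = 250
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        Yp = yc[idx].T  # n x b, centered response permutations
        C = Gc.T @ Yp
        stat = _adaptive_burden_stats(C, col_ss, v, K, s_ss, y_ss, r_crit)
        exceed += int((stat >= obs - 1e-12).sum())
        done += b
    pval = (1 + exceed) / (1 + n_perm)
    return burden, float(pval)


@dataclass
class Instrument:
    """One selected instrument: a genotype column or a burden pseudo-variant."""

    id: str
    kind: str  # single_variant | burden_low | burden_rare
    p_value: float
    position: int
    values: np.ndarray = field(repr=False)


@dataclass
class IVSet:
    """Selected instruments for one gene (at most ``max_k``, decorrelated)."""

    gene_id: str
    instruments: list[Instrument] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [iv.id for iv in self.instruments]

    def matrix(self, n_samples: int) -> np.ndarray:
        if not self.instruments:
            return np.empty((n_samples, 0))
        return np.column_stack([iv.values for iv in self.instruments])

    def __len__(self) -> int:
        return len(self.instruments)


def select_ivs(gene_id: str, candidates: list[Instrument], max_k: int = 3,
               max_corr: float = 0.3) -> IVSet:
    """Greedy decorrelated selection in ascending p-value order.

    Candidates must already satisfy the significance threshold. Ties in
    p-value break by genomic position (ascending), then by id. A
    candidate is admitted iff its absolute Pearson correlation with every
    already-admitted instrument is strictly below ``max_corr``.
    """
    chosen: list[Instrument] = []
    for cand in sorted(candidates, key=lambda c: (c.p_value, c.position, c.id)):
        if len(chosen) >= max_k:
            break
        ok = True
        for inc in chosen:
            a = cand.values - cand.values.mean()
            b = inc.values - inc.values.mean()
            na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
            r = 0.0 if na == 0 or nb == 0 else abs(float(a @ b) / (na * nb))
            if r >= max_corr:
                ok = False
                break
        if ok:
            chosen.append(cand)
    return IVSet(gene_id, chosen)


class IVSelector(BaseEstimator):
    """Discover cis instruments for every gene.

    Parameters
    ----------
    alpha : float
        Family-wise candidacy level per gene; each gene's tests are
        Bonferroni-corrected within its own cis window (``alpha /
        n_tests``).
    flank : int
        Cis window flank in base pairs (default 1000).
    max_k, max_corr : selection caps (default 3 instruments, |r| < 0.3).
    alpha0 : nominal level of the adaptive flip inside the burden test.
    n_perm : permutations for the burden test.
    pool_classes : if True, low-MAF and rare variants each form their own
        burden (one candidate per class per gene).
    seed : base seed for permutation tests.

    Attributes (after ``fit``)
    --------------------------
    ivsets_ : dict gene_id -> IVSet
    pool_ : n x K matrix of all distinct selected instrument columns
    pool_ids_ : instrument IDs aligned with ``pool_`` columns
    pool_index_ : dict gene_id -> list of pool column indices
    table_ : tidy per-gene instrument table (gene, instrument, class, p)
    """

    def __init__(self, alpha: float = 0.05, flank: int = 1000, max_k: int = 3,
                 max_corr: float = 0.3, alpha0: float = 0.1, n_perm: int = 1000,
                 seed: int = 0):
        self.alpha = alpha
        self.flank = flank
        self.max_k = max_k
        self.max_corr = max_corr
        self.alpha0 = alpha0
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, expr: ExpressionMatrix, genotypes: GenotypeMatrix,
            annotations: list[GeneAnnotation], y=None) -> "IVSelector":
        if expr.sample_ids != genotypes.sample_ids:
            raise ValueError("expression and genotype sample IDs must match")
        ann = {a.gene_id: a for a in annotations}
        maf = genotypes.compute_maf()
        if np.isnan(genotypes.dosages).any():
            raise ValueError("genotypes must be imputed before IV discovery")
        positions = np.array([v.position for v in genotypes.variants])
        chroms = np.array([v.chromosome for v in genotypes.variants])

        ivsets: dict[str, IVSet] = {}
        rows = []
        for k, gene in enumerate(expr.gene_ids):
            if gene not in ann:
                ivsets[gene] = IVSet(gene)
                continue
            chrom, lo, hi = cis_window(ann[gene], self.flank)
            in_win = (chroms == chrom) & (positions >= lo) & (positions <= hi)
            idx = np.nonzero(in_win)[0]
            y_k = expr.values[:, k]
            candidates: list[Instrument] = []
            common_idx = [j for j in idx if classify_maf(maf[j]) == "common"]
            low_idx = [j for j in idx if classify_maf(maf[j]) == "low"]
            rare_idx = [j for j in idx if classify_maf(maf[j]) == "rare"]
            n_tests = len(common_idx) + (1 if low_idx else 0) + (1 if rare_idx else 0)
            if n_tests == 0:
                ivsets[gene] = IVSet(gene)
                continue
            alpha_gene = self.alpha / n_tests

            for j in common_idx:
                x = genotypes.dosages[:, j]
                _, p = marginal_test(y_k, x)
                if p < alpha_gene:
                    candidates.append(Instrument(
                        genotypes.variants[j].id, "single_variant", p,
                        genotypes.variants[j].position, x.copy()))
            for label, group in (("low", low_idx), ("rare", rare_idx)):
                if not group:
                    continue
                sub_seed = int(np.random.SeedSequence((self.seed, k, 0 if label == "low" else 1))
                               .generate_state(1)[0] % (2 ** 31))
                burden, p = asum_test(y_k, genotypes.dosages[:, group],
                                      alpha0=self.alpha0, n_perm=self.n_perm,
                                      seed=sub_seed)
                if p < alpha_gene:
                    candidates.append(Instrument(
                        f"{gene}_burden_{label}", f"burden_{label}", p, lo, burden))
            ivsets[gene] = select_ivs(gene, candidates, self.max_k, self.max_corr)
            for iv in ivsets[gene].instruments:
                rows.append((gene, iv.id, iv.kind, iv.p_value))

        self.ivsets_ = ivsets
        self.table_ = pd.DataFrame(rows, columns=["gene", "instrument", "class", "p_value"])

        # pooled genome-wide instrument matrix (distinct columns, stable order)
        pool_ids: list[str] = []
        pool_cols: list[np.ndarray] = []
        pool_pos: dict[str, int] = {}
        pool_index: dict[str, list[int]] = {}
        for gene in expr.gene_ids:
            pool_index[gene] = []
            for iv in ivsets[gene].instruments:
                if iv.id not in pool_pos:
                    pool_pos[iv.id] = len(pool_ids)
                    pool_ids.append(iv.id)
                    pool_cols.append(iv.values)
                pool_index[gene].append(pool_pos[iv.id])
        self.pool_ids_ = pool_ids
        self.pool_ = (np.column_stack(pool_cols) if pool_cols
                      else np.empty((expr.n_samples, 0)))
        self.pool_index_ = pool_index
        return self
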