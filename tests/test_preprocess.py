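"""Expression filters, TMM, genotype QC, PCs and residualization."""

import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

from ivgrn import (
    ExpressionMatrix,
    filter_genes_gtex,
    filter_genes_tcga,
    genotype_pcs,
    impute_major_allele,
    log2_transform,
    qc_genotypes,
    residualize,
    tmm_normalize,
)
from ivgrn.preprocess import hwe_chisq_pvalue, hwe_exact_pvalue, median_of_ratios_factors

from conftest import make_genotypes


def expr_from(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionMatrix(values, [f"s{i}" for i in range(n)],
                            [f"{prefix}{j}" for j in range(p)])


class TestGeneFilters:
    def test_gtex_both_thresholds_inclusive(self):
        # 10 samples; gene0: TPM 0.2 in 3 samples, reads 10 in 2 samples -> kept
        # gene1: TPM 0.2 in 1 sample only -> removed
        counts = np.zeros((10, 2))
        counts[:2, 0] = 10
        counts[:2, 1] = 10
        tpm = np.zeros((10, 2))
        tpm[:3, 0] = 0.2
        tpm[0, 1] = 0.2
        keep, report = filter_genes_gtex(expr_from(counts), expr_from(tpm))
        assert keep == ["g0"]
        assert ("g1", "low_expression_gtex") in report.genes_removed

    def test_gtex_high_expression_trivially_kept(self):
        counts = np.full((5, 1), 100.0)
        tpm = np.full((5, 1), 5.0)
        keep, _ = filter_genes_gtex(expr_from(counts), expr_from(tpm))
        assert keep == ["g0"]

    def test_gtex_mismatched_ids_is_error(self):
        with pytest.raises(ValueError):
            filter_genes_gtex(expr_from(np.zeros((3, 1))),
                              expr_from(np.zeros((3, 1)), prefix="x"))

    def test_tcga_rules_and_boundary(self):
        n = 10
        vals = np.zeros((n, 3))
        vals[:, 0] = 260_000          # total 2.6e6, present everywhere -> kept
        vals[0, 1] = 1_000            # total 1e3, zero in 90% -> removed (both clauses)
        vals[:, 2] = 250_000          # total exactly 2.5e6 -> kept ("less than" is strict)
        keep, report = filter_genes_tcga(expr_from(vals))
        assert keep == ["g0", "g2"]
        assert report.counts["low_expression_tcga"] == 1


class TestTMM:
    def test_identical_samples_all_factors_one(self, rng):
        base = rng.integers(10, 1000, size=1000).astype(float)
        counts = expr_from(np.tile(base, (4, 1)))
        np.testing.assert_allclose(tmm_normalize(counts), 1.0, atol=1e-12)

    def test_pure_library_size_difference_gives_factor_one(self, rng):
        # TMM corrects composition bias, not library size: doubling every
        # count leaves the library-normalized M-values at zero.
        base = rng.integers(10, 1000, size=1000).astype(float)
        counts = expr_from(np.vstack([base, 2.0 * base]))
        np.testing.assert_allclose(tmm_normalize(counts), 1.0, atol=1e-9)

    def test_single_outlier_gene_is_trimmed_away(self, rng):
        base = rng.integers(100, 200, size=1000).astype(float)
        other = base.copy()
        other[0] = base[0] * 64  # one wildly different gene among 1000
        counts = expr_from(np.vstack([base, other]))
        factors = tmm_normalize(counts)
        # the outlier falls in the 30% M-trim, so the factors compensate
        # exactly for the library-size inflation it causes: effective
        # library sizes equalize the non-outlier genes' normalized values
        out = log2_transform(counts, factors)
        np.testing.assert_allclose(out.values[0, 1:], out.values[1, 1:], atol=5e-3)

    def test_scale_invariance(self, rng):
        counts = expr_from(rng.integers(1, 500, size=(4, 300)).astype(float))
        f1 = tmm_normalize(counts)
        f2 = tmm_normalize(expr_from(counts.values * 7.0))
        np.testing.assert_allclose(f1, f2, atol=1e-9)

    def test_all_zero_sample_is_error(self):
        counts = expr_from(np.array([[1.0, 2.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="all-zero"):
            tmm_normalize(counts)

    def test_matches_edger_calcnormfactors(self, rng, tmp_path):
        # independent oracle: edgeR's TMM implementation on a small matrix
        counts = rng.negative_binomial(5, 0.01, size=(5, 400)).astype(float) + 1
        expr = expr_from(counts)
        ours = tmm_normalize(expr, reference="s0")
        mat = "\n".join(",".join(str(int(v)) for v in row) for row in counts.T)
        (tmp_path / "counts.csv").write_text(mat + "\n")
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.csv("{tmp_path}/counts.csv", header=FALSE))
            f <- calcNormFactors(x, method="TMM", refColumn=1)
            cat(sprintf("%.12f", f), sep="\\n")
        """)
        try:
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, timeout=300)
        except (FileNotFoundError, subprocess.TimeoutExpired):
            pytest.skip("Rscript unavailable")
        if out.returncode != 0:
            pytest.skip(f"edgeR unavailable: {out.stderr[-200:]}")
        theirs = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(ours, theirs, rtol=1e-6)


class TestLog2Transform:
    def test_zero_count_maps_to_zero(self):
        counts = expr_from(np.array([[0.0, 10.0]]))
        out = log2_transform(counts)
        assert out.values[0, 0] == 0.0

    def test_monotone_in_count(self):
        a = log2_transform(expr_from(np.array([[5.0, 100.0]])))
        b = log2_transform(expr_from(np.array([[10.0, 100.0]])))
        assert b.values[0, 0] > a.values[0, 0]

    def test_proportional_samples_identical_profiles(self, rng):
        base = rng.integers(1, 500, size=200).astype(float)
        counts = expr_from(np.vstack([base, 3.0 * base]))
        out = log2_transform(counts, np.ones(2))
        np.testing.assert_allclose(out.values[0], out.values[1], atol=1e-9)


class TestHWE:
    def test_exact_hwe_proportions_not_rejected(self):
        # 25/50/25 is exactly p=0.5 HWE: chi-square 0, p = 1
        assert hwe_chisq_pvalue(25, 50, 25) == pytest.approx(1.0)

    def test_no_heterozygotes_strongly_rejected(self):
        # AA=50, aa=50: expected 25/50/25, chi-square = 100
        p = hwe_chisq_pvalue(50, 0, 50)
        assert p < 1e-20

    def test_monomorphic_is_p_one(self):
        assert hwe_chisq_pvalue(100, 0, 0) == 1.0
        assert hwe_exact_pvalue(100, 0, 0) == 1.0

    def test_exact_matches_enumeration_oracle(self):
        # full enumeration of the conditional distribution of the
        # heterozygote count given allele counts, via log-probabilities
        from math import lgamma, exp
        n0, n1, n2 = 20, 40, 10
        n = n0 + n1 + n2
        rare = 2 * n2 + n1 if n2 <= n0 else 2 * n0 + n1

        def logp(het):
            hom_r = (rare - het) // 2
            hom_c = n - het - hom_r
            return (lgamma(n + 1) - lgamma(hom_r + 1) - lgamma(het + 1)
                    - lgamma(hom_c + 1) + het * np.log(2)
                    + lgamma(rare + 1) + lgamma(2 * n - rare + 1) - lgamma(2 * n + 1))
        hets = [h for h in range(rare % 2, rare + 1, 2) if (rare - h) // 2 + h <= n]
        ps = {h: exp(logp(h)) for h in hets}
        total = sum(ps.values())
        obs = ps[n1]
        expected = sum(v for v in ps.values() if v <= obs * (1 + 1e-12)) / total
        assert hwe_exact_pvalue(n0, n1, n2) == pytest.approx(expected, rel=1e-9)

    def test_chisq_vs_exact_rejection_agreement(self, rng):
        # 500 random genotype-count triples at n=200: the two tests agree
        # in their reject/keep decision at alpha=1e-4 except in a narrow
        # boundary band around the cutoff
        alpha = 1e-4
        disagreements = 0
        explained = 0
        for _ in range(500):
            p_true = rng.uniform(0.05, 0.95)
            f = rng.uniform(-0.2, 0.5)  # inbreeding-style distortion
            p_hom = np.clip(p_true ** 2 + f * p_true * (1 - p_true), 0, 1)
            p_het = np.clip(2 * p_true * (1 - p_true) * (1 - f), 0, 1)
            p_alt = max(0.0, 1 - p_hom - p_het)
            counts = rng.multinomial(200, [p_hom, p_het, p_alt] /
                                     np.array([p_hom + p_het + p_alt]))
            pc = hwe_chisq_pvalue(*counts)
            pe = hwe_exact_pvalue(*counts)
            if (pc < alpha) != (pe < alpha):
                disagreements += 1
                near_boundary = min(pc, pe) > alpha / 100 and max(pc, pe) < alpha * 100
                n0, n1, n2 = counts
                low_mac = min(2 * n0 + n1, 2 * n2 + n1) < 20
                if near_boundary or low_mac:
                    explained += 1
        # every disagreement is either borderline or in the low-count
        # regime where the 1-df approximation is anticonservative
        assert disagreements == explained
        assert disagreements <= 25


class TestGenotypeQC:
    def test_filter_order_and_mac_boundary(self, rng):
        n = 100
        cols = []
        # v0: fine (exact HWE at p=0.5)
        v0 = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=float)
        # v1: >10% missing -> removed first
        v1 = v0.copy(); v1[:20] = np.nan
        # v2: HWE violation (no hets)
        v2 = np.array([0] * 50 + [2] * 50, dtype=float)
        # v3: MAC exactly 5 -> kept (boundary inclusive)
        v3 = np.zeros(n); v3[:5] = 1
        # v4: MAC 4 -> removed
        v4 = np.zeros(n); v4[:4] = 1
        g = make_genotypes(np.column_stack([v0, v1, v2, v3, v4]))
        out, report = qc_genotypes(g)
        assert out.variant_ids == ["v0", "v3"]
        reasons = dict(report.variants_removed)
        assert reasons["v1"] == "variant_missing_rate"
        assert reasons["v2"] == "hwe_violation"
        assert reasons["v4"] == "minor_allele_count"

    def test_sample_missing_filter_and_report_reconciles(self):
        d = np.zeros((10, 3))
        d[:, 0] = [0, 1] * 5
        d[:, 1] = [1, 0] * 5
        d[:, 2] = [0, 0, 1, 1, 0, 0, 1, 1, 0, 1]
        d[0, :2] = np.nan  # sample 0 missing 2/3 > 10%
        g = make_genotypes(d)
        out, report = qc_genotypes(g, min_mac=1, hwe_alpha=1e-10)
        assert out.n_samples == 9
        assert ("s0", "sample_missing_rate") in report.samples_removed
        assert report.counts["samples_retained"] + len(
            [s for s, _ in report.samples_removed]) == 10

    def test_all_variants_removed_is_error(self):
        g = make_genotypes(np.zeros((20, 2)))
        with pytest.raises(ValueError, match="no variants survive"):
            qc_genotypes(g)

    def test_maf_computed_on_retained(self):
        d = np.zeros((50, 1)); d[:10, 0] = 1
        g = make_genotypes(d)
        out, _ = qc_genotypes(g)
        assert out.variants[0].maf == pytest.approx(0.1)


class TestImputation:
    def test_alt_minor_missing_becomes_zero(self):
        d = np.zeros((20, 1)); d[:4, 0] = 1; d[5, 0] = np.nan
        g = make_genotypes(d)
        out = impute_major_allele(g)
        assert out.dosages[5, 0] == 0.0

    def test_alt_major_missing_becomes_two(self):
        d = np.full((20, 1), 2.0); d[:2, 0] = 0; d[5, 0] = np.nan
        out = impute_major_allele(make_genotypes(d))
        assert out.dosages[5, 0] == 2.0

    def test_complete_matrix_unchanged(self):
        d = np.array([[0.0, 2.0], [1.0, 1.0]])
        out = impute_major_allele(make_genotypes(d))
        np.testing.assert_array_equal(out.dosages, d)


class TestGenotypePCs:
    def test_columns_orthogonal(self, rng):
        g = make_genotypes(rng.binomial(2, 0.3, size=(60, 40)).astype(float))
        pcs = genotype_pcs(g, k=3)
        gram = pcs.T @ pcs
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_two_subpopulations_separate_on_pc1(self, rng):
        # allele-frequency difference 0.4 across 200 variants, n=100
        freqs_a = rng.uniform(0.1, 0.5, 200)
        freqs_b = np.clip(freqs_a + 0.4, 0, 0.95)
        d = np.vstack([rng.binomial(2, freqs_a, size=(50, 200)),
                       rng.binomial(2, freqs_b, size=(50, 200))]).astype(float)
        pcs = genotype_pcs(make_genotypes(d), k=2)
        labels = np.array([0] * 50 + [1] * 50)
        side = pcs[:, 0] > np.median(pcs[:, 0])
        assert (side == labels).all() or (side == 1 - labels).all()

    def test_k_zero_gives_empty_matrix(self, toy_genotypes):
        g = impute_major_allele(toy_genotypes)
        assert genotype_pcs(g, k=0).shape == (2, 0)


class TestResidualize:
    def test_orthogonal_covariate_only_centers(self, rng):
        import pandas as pd
        n = 200
        y = rng.normal(size=(n, 3))
        x = rng.normal(size=n)
        x -= x.mean()
        # project y to be exactly orthogonal to x, then residualize
        y0 = y - np.outer(x, (x @ y) / (x @ x))
        cov = pd.DataFrame({"c": x}, index=[f"s{i}" for i in range(n)])
        expr = ExpressionMatrix(y0, [f"s{i}" for i in range(n)], list("abc"))
        out = residualize(expr, cov)
        np.testing.assert_allclose(out.values, y0 - y0.mean(axis=0), atol=1e-9)

    def test_residuals_orthogonal_to_design(self, rng):
        import pandas as pd
        n = 150
        idx = [f"s{i}" for i in range(n)]
        cov = pd.DataFrame({
            "sex": rng.choice(["M", "F"], n),
            "age": rng.normal(50, 8, n),
        }, index=idx)
        expr = ExpressionMatrix(rng.normal(size=(n, 4)), idx, list("abcd"))
        out = residualize(expr, cov)
        sex = (cov["sex"] == "M").to_numpy(float)
        for v in (sex, cov["age"].to_numpy(), np.ones(n)):
            np.testing.assert_allclose(out.values.T @ v, 0.0, atol=1e-7)

    def test_known_effect_removed(self, rng):
        import pandas as pd
        n = 500
        idx = [f"s{i}" for i in range(n)]
        sex = rng.integers(0, 2, n)
        noise = rng.normal(size=n)
        y = 2.0 * sex + noise
        cov = pd.DataFrame({"sex": np.where(sex == 1, "M", "F")}, index=idx)
        expr = ExpressionMatrix(y[:, None], idx, ["g"])
        out = residualize(expr, cov)
        assert out.values[:, 0].var() == pytest.approx(noise.var(), rel=0.05)

    def test_idempotent(self, rng):
        import pandas as pd
        n = 80
        idx = [f"s{i}" for i in range(n)]
        cov = pd.DataFrame({"batch": rng.choice(list("xyz"), n)}, index=idx)
        expr = ExpressionMatrix(rng.normal(size=(n, 3)), idx, list("abc"))
        once = residualize(expr, cov)
        twice = residualize(once, cov)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)

    def test_collinear_columns_dropped_not_fatal(self, rng):
        import pandas as pd
        n = 50
        idx = [f"s{i}" for i in range(n)]
        x = rng.normal(size=n)
        cov = pd.DataFrame({"a": x, "b": 2 * x}, index=idx)
        expr = ExpressionMatrix(rng.normal(size=(n, 2)), idx, ["g1", "g2"])
        out = residualize(expr, cov)
        np.testing.assert_allclose(out.values.T @ x, 0.0, atol=1e-7)


def test_median_of_ratios_factors_proportional_libraries(rng):
    base = rng.integers(5, 500, size=300).astype(float)
    counts = ExpressionMatrix(np.vstack([base, 2 * base]), ["a", "b"],
                              [f"g{j}" for j in range(300)])
    f = median_of_ratios_factors(counts)
    np.testing.assert_allclose(f, 1.0, atol=1e-9)
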