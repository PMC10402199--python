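import numpy as np
import pytest

from ivgrn import ExpressionMatrix, GenotypeMatrix, VariantInfo


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_expression():
    return ExpressionMatrix(
        np.array([[10.0, 0.0], [5.0, 6.0], [0.0, 2.0]]),
        ["s1", "s2", "s3"],
        ["geneA", "geneB"],
    )


def make_genotypes(dosages, positions=None, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=float)
    n, q = dosages.shape
    positions = positions or [1000 * (j + 1) for j in range(q)]
    variants = [VariantInfo(f"v{j}", chrom, positions[j], "A", "G") for j in range(q)]
    return GenotypeMatrix(dosages, variants, [f"s{i}" for i in range(n)])


@pytest.fixture
def toy_genotypes():
    return make_genotypes([[0, 2], [1, np.nan]])
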