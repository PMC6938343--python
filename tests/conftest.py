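import numpy as np
import pytest

from pleiopheno.model import GenotypeMatrix, Variant


def make_matrix(dosage, ids=None, rng=None, chrom="1"):
    """GenotypeMatrix from a plain dosage array with synthetic metadata."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    ids = ids or [f"v{j}" for j in range(m)]
    variants = [Variant(ids[j], chrom, 1000 * (j + 1), ("A", "G"), "G") for j in range(m)]
    samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(samples, variants, dosage)


def random_matrix(rng, n=12, m=6, missing_rate=0.0):
    dosage = rng.integers(0, 3, size=(n, m)).astype(float)
    if missing_rate:
        mask = rng.random((n, m)) < missing_rate
        mask[0, :] = False
        dosage[mask] = np.nan
    # a het in every column keeps both alleles observable in allele-pair
    # formats (PED), so text round trips preserve the metadata
    dosage[0, :] = 1.0
    return make_matrix(dosage)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
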