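import numpy as np
import pytest

from ctpr.io_formats import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_genotypes(rng, n, P, maf_low=0.1, maf_high=0.5, missing_rate=0.0):
    """Raw hard-call GenotypeMatrix with optional missingness."""
    mafs = rng.uniform(maf_low, maf_high, size=P)
    dosages = rng.binomial(2, mafs, size=(n, P)).astype(float)
    if missing_rate:
        mask = rng.random((n, P)) < missing_rate
        dosages[mask] = np.nan
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array([f"rs{j}" for j in range(P)]),
        chrom=np.array(["1"] * P),
        pos=np.arange(1, P + 1),
        allele1=np.array(["A"] * P),
        allele2=np.array(["C"] * P),
        sample_ids=np.array([f"s{i}" for i in range(n)]),
    )


def standardized_design(rng, n, P):
    """Gaussian design with exact column mean 0 and sum of squares n."""
    X = rng.standard_normal((n, P))
    X -= X.mean(axis=0)
    X /= np.sqrt((X**2).sum(axis=0) / n)
    return X


@pytest.fixture
def geno_factory(rng):
    def _make(n=40, P=12, **kw):
        return make_genotypes(rng, n, P, **kw)

    return _make
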