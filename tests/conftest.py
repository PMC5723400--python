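import numpy as np
import pytest

from clonalscape.genotype_io import GenotypeMatrix


def make_matrix(calls, site_id="s1", species="sp"):
    """Build a GenotypeMatrix from a nested list of ('A','B') / None calls."""
    n = len(calls)
    l = len(calls[0]) if n else 0
    return GenotypeMatrix(
        site_id=site_id,
        species=species,
        sample_ids=[f"{site_id}_{i + 1}" for i in range(n)],
        locus_ids=[f"L{j + 1}" for j in range(l)],
        calls=[list(row) for row in calls],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def matrix_factory():
    return make_matrix


def random_matrix(rng, n_samples, n_loci, n_alleles=3, missing_rate=0.0):
    """Random small genotype matrix for oracle comparisons."""
    calls = []
    for _ in range(n_samples):
        row = []
        for _ in range(n_loci):
            if rng.random() < missing_rate:
                row.append(None)
            else:
                a, b = sorted(rng.integers(1, n_alleles + 1, size=2))
                row.append((str(a), str(b)))
        calls.append(row)
    return make_matrix(calls)
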