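import numpy as np
import pandas as pd
import pytest

from rohkin.genotype_io import GenotypeMatrix


def make_matrix(calls, positions=None, chroms=None, sample_ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a (samples x variants) array of codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_variants = calls.shape
    if positions is None:
        positions = np.arange(1, n_variants + 1) * 10_000
    if chroms is None:
        chroms = ["1"] * n_variants
    variants = pd.DataFrame(
        {
            "chrom": [str(c) for c in chroms],
            "pos": np.asarray(positions, dtype=np.int64),
            "id": [f"snp{i}" for i in range(n_variants)],
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
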