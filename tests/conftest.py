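import numpy as np
import pandas as pd
import pytest

from meqtlmap.io import GenotypeSet
from meqtlmap.simulate import ArchitectureSpec, simulate_genotypes, simulate_methylome


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_genotypes() -> GenotypeSet:
    """10 individuals x 4 variants with hand-written dosages."""
    dosage = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 0, 2],
            [2, 0, 1, 1],
            [0, 2, 2, 0],
            [1, 1, 1, 1],
            [2, 0, 0, 2],
            [0, 1, 2, 0],
            [1, 2, 1, 1],
            [2, 1, 0, 2],
            [1, 1, 1, 0],
        ],
        dtype=float,
    )
    p = dosage.mean(axis=0) / 2
    return GenotypeSet(
        variant_id=np.array([f"v{i}" for i in range(4)], dtype=object),
        chrom=np.array(["1", "1", "1", "2"], dtype=object),
        pos=np.array([100, 5000, 900_000, 100]),
        dosage=dosage,
        maf=np.minimum(p, 1 - p),
        individual_ids=[f"b{i}" for i in range(10)],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """100 individuals, 600 variants, 80 CpGs with 30% strong cis effects."""
    spec = ArchitectureSpec(
        n_individuals=100,
        n_variants=600,
        n_cpgs=80,
        frac_cis_cpgs=0.3,
        cis_beta_sd=3.0,
        cis_beta_min=8.0,
        seed=7,
    )
    genotypes = simulate_genotypes(spec)
    samples, meta, truth = simulate_methylome(genotypes, spec)
    return spec, genotypes, samples, meta, truth
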