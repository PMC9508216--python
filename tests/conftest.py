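import numpy as np
import pandas as pd
import pytest

from spindlepgs.synth import SimGenConfig, simulate_genotypes
from spindlepgs.types import GenotypeDataset


@pytest.fixture(scope="session")
def small_cohort() -> GenotypeDataset:
    """200 individuals x 500 variants with moderate LD, clean of relatedness."""
    return simulate_genotypes(
        SimGenConfig(
            n_individuals=200, n_variants=500, ld_block_size=5, ld_rho=0.4, seed=42
        )
    )


@pytest.fixture()
def covariates_5000() -> pd.DataFrame:
    """sex + age + ten synthetic population-structure axes for n=5000."""
    rng = np.random.default_rng(123)
    n = 5000
    cols = {"sex": rng.integers(0, 2, n).astype(float), "age": rng.normal(35, 10, n)}
    for k in range(10):
        cols[f"PC{k + 1}"] = rng.normal(0.0, 1.0, n)
    return pd.DataFrame(cols)


def make_dataset(dosages, positions=None, chrom=1, mafs_irrelevant=None):
    """Hand-build a GenotypeDataset from a dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    individuals = pd.DataFrame(
        {"iid": [f"s{i}" for i in range(n)], "sex": [1] * n}
    )
    variants = pd.DataFrame(
        {
            "snp": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": positions if positions is not None else np.arange(m) * 10_000 + 1,
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    return GenotypeDataset(dosages, individuals, variants)
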