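"""Synthetic biallelic genotypes: HWE dosages, block LD, cryptic relatedness.

Genotypes are built from two independent haplotypes per individual, each a
thresholded latent Gaussian. Hardy-Weinberg equilibrium therefore holds
exactly per variant, and linkage disequilibrium is induced within
fixed-size blocks through an equicorrelated latent factor (a Gaussian
copula), which is the simplest structure that exercises both LD pruning and
p-value clumping. Cryptic relatedness is created by copying one haplotype
between the members of a pair, giving an expected genome-sharing of
pi-hat ~ 0.5 (a parent-offspring-like pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..types import GenotypeDataset

# non-strand-ambiguous allele pairs (no A/T or C/G)
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


@dataclass
class SimGenConfig:
    n_individuals: int = 200
    n_variants: int = 1_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.0
    n_related_pairs: int = 0
    concordant_fraction: float = 0.5
    seed: int = 0
    missing_rate: float = 0.0
    palindromic_fraction: float = 0.0
    chrom: int = 1
    pos_start: int = 1_000_000
    pos_spacing: int = 10_000

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.concordant_fraction <= 1.0):
            raise ValueError("concordant_fraction must be in [0, 1]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.n_variants < self.ld_block_size:
            raise ValueError("n_variants must be >= ld_block_size")
        if 2 * self.n_related_pairs > self.n_individuals:
            raise ValueError("too many related pairs for cohort size")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


def simulate_genotypes(config: SimGenConfig) -> GenotypeDataset:
    """Draw a dosage matrix under the configured HWE/LD/relatedness model.

    Dosages count copies of ``a1`` (the minor/effect allele, frequency equal
    to the sampled MAF). Related pairs occupy the *last* ``2*n_related_pairs``
    rows as consecutive (even, odd) index pairs sharing one haplotype.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_variants

    mafs = rng.uniform(*config.maf_range, size=m)
    thresholds = stats.norm.ppf(mafs)
    block_of = np.arange(m) // config.ld_block_size
    n_blocks = int(block_of.max()) + 1
    rho = config.ld_rho

    def draw_haplotypes() -> np.ndarray:
        eps = rng.standard_normal((n, m))
        if rho > 0:
            shared = rng.standard_normal((n, n_blocks))
            z = np.sqrt(rho) * shared[:, block_of] + np.sqrt(1 - rho) * eps
        else:
            z = eps
        return (z < thresholds).astype(np.int8)

    hap1 = draw_haplotypes()
    hap2 = draw_haplotypes()

    for k in range(config.n_related_pairs):
        i = n - 2 * (k + 1)
        j = i + 1
        hap1[j] = hap1[i]

    dosages = (hap1 + hap2).astype(float)
    if config.missing_rate > 0:
        dosages[rng.random((n, m)) < config.missing_rate] = np.nan

    n_pal = int(round(config.palindromic_fraction * m))
    pal_idx = rng.permutation(m)[:n_pal]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    a1 = np.array([_ALLELE_PAIRS[k][0] for k in pair_idx], dtype=object)
    a2 = np.array([_ALLELE_PAIRS[k][1] for k in pair_idx], dtype=object)
    for j in pal_idx:
        pal = _PALINDROMIC_PAIRS[j % len(_PALINDROMIC_PAIRS)]
        a1[j], a2[j] = pal

    individuals = pd.DataFrame(
        {"iid": [f"ind{i:05d}" for i in range(n)], "sex": rng.integers(1, 3, size=n)}
    )
    variants = pd.DataFrame(
        {
            "snp": [f"rs{j + 1:06d}" for j in range(m)],
            "chrom": config.chrom,
            "pos": config.pos_start + np.arange(m) * config.pos_spacing,
            "a1": a1,
            "a2": a2,
        }
    )
    return GenotypeDataset(dosages, individuals, variants)
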