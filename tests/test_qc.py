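"""Quality-control cascade: exact HWE test, filters, pruning, relatedness,
PCA outliers."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spindlepgs.qc import (
    QCReport,
    QCThresholds,
    high_quality_set,
    hwe_exact_test,
    ld_prune,
    pairwise_r2,
    pca_outlier_filter,
    pi_hat_matrix,
    relatedness_filter,
    run_qc,
    sample_qc,
    variant_qc,
)
from spindlepgs.synth import SimGenConfig, simulate_genotypes

from conftest import make_dataset


def hwe_enumeration_oracle(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact-rational full enumeration over heterozygote counts conditional
    on allele counts (independent of the production implementation)."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n - n_a

    def prob(h: int) -> Fraction:
        ha = (n_a - h) // 2
        hb = (n_b - h) // 2
        # multinomial over genotypes x 2^het haplotype phasings / allele perm
        num = (
            Fraction(comb(n, ha))
            * comb(n - ha, hb)
            * comb(n - ha - hb, h)
            * 2**h
        )
        den = Fraction(comb(2 * n, n_a))
        return num / den

    hets = [h for h in range(min(n_a, n_b) % 2, min(n_a, n_b) + 1, 2)]
    probs = {h: prob(h) for h in hets}
    total = sum(probs.values())
    probs = {h: p / total for h, p in probs.items()}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHWEExact:
    def test_modal_configuration_p_is_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_complete_het_deficit_fails_filter(self):
        assert hwe_exact_test(50, 0, 50) < 1e-6

    def test_monomorphic_variant_is_trivially_conformant(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(2, 201))
            hom1 = int(rng.integers(0, n + 1))
            het = int(rng.integers(0, n - hom1 + 1))
            hom2 = n - hom1 - het
            assert hwe_exact_test(hom1, het, hom2) == pytest.approx(
                hwe_enumeration_oracle(hom1, het, hom2), abs=1e-12
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 5, 5)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        hom1=st.integers(min_value=0, max_value=120),
        het=st.integers(min_value=0, max_value=120),
        hom2=st.integers(min_value=0, max_value=120),
    )
    def test_property_valid_probability_and_symmetry(self, hom1, het, hom2):
        if hom1 + het + hom2 == 0:
            return
        p = hwe_exact_test(hom1, het, hom2)
        assert 0.0 < p <= 1.0
        # the test is symmetric in the two homozygote classes
        assert p == pytest.approx(hwe_exact_test(hom2, het, hom1), abs=1e-12)


class TestSampleQC:
    def test_high_missingness_removed(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, (50, 200)).astype(float)
        dos[0, : int(200 * 0.03)] = np.nan  # 3% missing
        ds = make_dataset(dos)
        clean, report = sample_qc(ds)
        assert ("s0", "missingness") in report.removed_individuals
        assert clean.n_individuals == ds.n_individuals - len(
            report.removed_individuals
        )

    def test_clean_individual_retained(self):
        # HWE genotypes at MAF 0.5: expected het 0.5, all individuals typical
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=100, n_variants=2000,
                         maf_range=(0.45, 0.5), seed=2)
        )
        clean, report = sample_qc(ds)
        assert len(report.removed_individuals) == 0

    def test_all_heterozygous_individual_removed(self):
        # at MAF 0.1 the expected het rate is 0.18; an all-het row deviates
        # by (1 - 0.18)/0.18 >> 0.2
        rng = np.random.default_rng(3)
        p = 0.1
        dos = rng.choice(
            [0.0, 1.0, 2.0], size=(60, 500),
            p=[(1 - p) ** 2, 2 * p * (1 - p), p**2],
        )
        dos[5, :] = 1.0
        ds = make_dataset(dos)
        _, report = sample_qc(ds)
        assert ("s5", "heterozygosity") in report.removed_individuals


class TestVariantQC:
    def test_rare_variant_removed(self):
        rng = np.random.default_rng(4)
        dos = rng.integers(0, 3, (300, 5)).astype(float)
        dos[:, 0] = 0.0
        dos[:3, 0] = 1.0  # MAF = 3/600 = 0.005
        ds = make_dataset(dos)
        _, report = variant_qc(ds)
        assert ("v0", "maf") in report.removed_variants

    def test_clean_variant_retained(self):
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=200, n_variants=50,
                         maf_range=(0.2, 0.3), seed=5)
        )
        clean, report = variant_qc(ds)
        assert len(report.removed_variants) == 0
        assert clean.n_variants == 50

    def test_high_missingness_variant_removed(self):
        rng = np.random.default_rng(6)
        dos = rng.choice(  # HWE at MAF 0.5, so only missingness can trigger
            [0.0, 1.0, 2.0], size=(100, 3), p=[0.25, 0.5, 0.25]
        )
        dos[:5, 1] = np.nan  # 5% missing
        ds = make_dataset(dos)
        _, report = variant_qc(ds)
        assert ("v1", "missingness") in report.removed_variants


class TestHighQualitySet:
    def test_criteria(self):
        rng = np.random.default_rng(7)
        p = 0.3
        dos = rng.choice(
            [0.0, 1.0, 2.0], size=(400, 4),
            p=[(1 - p) ** 2, 2 * p * (1 - p), p**2],
        )
        # v1: low MAF; v2: one missing call
        dos[:, 1] = 0.0
        dos[: int(2 * 0.15 * 400), 1] = 1.0  # MAF 0.15
        dos[0, 2] = np.nan
        ds = make_dataset(dos)
        hq = high_quality_set(ds)
        assert "v0" in hq and "v3" in hq
        assert "v1" not in hq  # MAF below 0.20
        assert "v2" not in hq  # missingness not zero


class TestLDPrune:
    def test_duplicate_variants_keep_one(self):
        rng = np.random.default_rng(8)
        col = rng.integers(0, 3, 100).astype(float)
        ds = make_dataset(np.column_stack([col, col]))
        kept = ld_prune(ds)
        assert len(kept) == 1

    def test_independent_variants_all_survive(self):
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=2000, n_variants=30, ld_rho=0.0, seed=9)
        )
        kept = ld_prune(ds)
        assert len(kept) == 30

    def test_ld_block_pruned_to_r2_constraint(self):
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=500, n_variants=10, ld_block_size=10,
                         ld_rho=0.9, seed=10)
        )
        kept = ld_prune(ds)
        assert 1 <= len(kept) < 10
        sel = ds.variants["snp"].isin(kept).to_numpy()
        r2 = pairwise_r2(ds.dosages[:, sel])
        np.fill_diagonal(r2, 0.0)
        assert r2.max() < 0.1  # exhaustive all-pairs check

    def test_unsorted_positions_rejected(self):
        ds = make_dataset(np.zeros((10, 3)) + 1.0, positions=[30, 20, 10])
        with pytest.raises(ValueError):
            ld_prune(ds)


class TestRelatedness:
    def test_duplicate_individual_removed(self):
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=50, n_variants=1000, seed=11)
        )
        dos = ds.dosages.copy()
        dos[1] = dos[0]
        dup = make_dataset(dos)
        grm = pi_hat_matrix(dup)
        assert grm[0, 1] > 0.9
        clean, report = relatedness_filter(dup, seed=3)
        removed = report.removed_individual_ids()
        assert len(removed & {"s0", "s1"}) == 1

    def test_half_sharing_pair_flagged(self):
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=40, n_variants=3000, n_related_pairs=1,
                         seed=12)
        )
        grm = pi_hat_matrix(ds)
        assert grm[38, 39] > 0.35  # expected ~0.5
        _, report = relatedness_filter(ds, seed=0)
        assert report.removed_individual_ids() & {"ind00038", "ind00039"}

    def test_unrelated_cohort_untouched(self):
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=80, n_variants=3000, seed=13)
        )
        _, report = relatedness_filter(ds, seed=0)
        assert report.removed_individuals == []


class TestPCAOutliers:
    def test_homogeneous_cohort_keeps_everyone(self):
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=100, n_variants=500, seed=14)
        )
        clean, pcs, report = pca_outlier_filter(ds)
        assert report.removed_individuals == []
        assert clean.n_individuals == 100

    def test_contaminant_individual_removed(self):
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=100, n_variants=500,
                         maf_range=(0.05, 0.2), seed=15)
        )
        dos = ds.dosages.copy()
        rng = np.random.default_rng(0)
        shift = rng.random(500) < 0.5
        dos[0, shift] = 2.0  # pile of alternate-frequency genotypes
        contaminated = make_dataset(dos)
        _, _, report = pca_outlier_filter(contaminated, sd_thresh=4.0)
        assert "s0" in report.removed_individual_ids()

    def test_pc_columns_orthogonal(self):
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=60, n_variants=400, seed=16)
        )
        _, pcs, _ = pca_outlier_filter(ds, n_pcs=10)
        x = pcs.drop(columns="iid").to_numpy()
        gram = x.T @ x
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()


class TestCascade:
    def test_fixed_point_and_count_consistency(self):
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=120, n_variants=1500, ld_rho=0.3,
                         ld_block_size=5, n_related_pairs=1,
                         missing_rate=0.001, seed=17)
        )
        clean, pcs, report = run_qc(ds, seed=1)
        assert (
            ds.n_individuals - len(report.removed_individuals)
            == clean.n_individuals
        )
        assert ds.n_variants - len(report.removed_variants) == clean.n_variants
        # idempotency: the cascade on its own output removes nothing
        clean2, _, report2 = run_qc(clean, seed=1)
        assert report2.removed_individuals == []
        assert report2.removed_variants == []
        assert clean2.n_individuals == clean.n_individuals

    def test_every_removal_has_one_reason(self):
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=80, n_variants=800, n_related_pairs=2,
                         seed=18)
        )
        _, _, report = run_qc(ds, seed=2)
        ids = [i for i, _ in report.removed_individuals]
        assert len(ids) == len(set(ids))
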