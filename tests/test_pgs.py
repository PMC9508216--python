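"""Polygenic scoring: harmonization, filtering, stratification, thresholds."""

import numpy as np
import pandas as pd
import pytest

from spindlepgs.pgs import (
    ThresholdGrid,
    clump_variants,
    harmonize_alleles,
    info_filter,
    restrict_to_region,
    score_individuals,
    split_by_concordance,
)
from spindlepgs.qc import pairwise_r2
from spindlepgs.synth import SimGenConfig, simulate_genotypes, simulate_summary_stats
from spindlepgs.types import GenotypeDataset

from conftest import make_dataset


def _stats(rows):
    """rows: (snp, a1, a2, or_, p) with fixed chrom/pos/info."""
    return pd.DataFrame(
        {
            "SNP": [r[0] for r in rows],
            "CHR": 1,
            "BP": np.arange(len(rows)) * 10_000 + 1,
            "A1": [r[1] for r in rows],
            "A2": [r[2] for r in rows],
            "OR": [r[3] for r in rows],
            "SE": 0.1,
            "P": [r[4] for r in rows],
            "INFO": 0.99,
        }
    )


class TestHarmonize:
    @pytest.fixture()
    def panel(self):
        dos = np.array([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]])
        ds = make_dataset(dos)
        ds.variants["a1"] = ["A", "A", "A"]
        ds.variants["a2"] = ["G", "G", "T"]
        return ds

    def test_direct_match_kept_unchanged(self, panel):
        stats = _stats([("v0", "A", "G", 1.5, 0.01)])
        h = harmonize_alleles(stats, panel)
        assert len(h) == 1 and not h["flip"].iloc[0]

    def test_swapped_alleles_flagged_for_flip(self, panel):
        stats = _stats([("v1", "G", "A", 1.5, 0.01)])
        h = harmonize_alleles(stats, panel)
        assert len(h) == 1 and h["flip"].iloc[0]

    def test_palindromic_variant_removed(self, panel):
        stats = _stats([("v2", "A", "T", 1.5, 0.01), ("v0", "A", "G", 1.2, 0.5)])
        h = harmonize_alleles(stats, panel)
        assert h["SNP"].tolist() == ["v0"]

    def test_incompatible_alleles_dropped(self, panel):
        stats = _stats([("v0", "C", "G", 1.5, 0.01)])
        assert harmonize_alleles(stats, panel).empty

    def test_zero_overlap_rejected(self, panel):
        stats = _stats([("nope", "A", "G", 1.5, 0.01)])
        with pytest.raises(ValueError, match="overlap"):
            harmonize_alleles(stats, panel)

    def test_flipped_representation_scores_identically(self):
        """Scoring the same data stored with swapped allele labels yields
        bit-identical scores."""
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=50, n_variants=40, seed=1)
        )
        scz, _ = simulate_summary_stats(ds.variants, 0.5, seed=2)
        mat1 = score_individuals(ds, scz)

        flipped = GenotypeDataset(
            2.0 - ds.dosages,
            ds.individuals.copy(),
            ds.variants.rename(columns={"a1": "a2", "a2": "a1"})[
                ["snp", "chrom", "pos", "a1", "a2"]
            ],
        )
        mat2 = score_individuals(flipped, scz)
        assert np.array_equal(
            mat1.scores.to_numpy(), mat2.scores.to_numpy()
        )


class TestInfoFilter:
    def test_boundary_semantics(self):
        stats = _stats([("a", "A", "G", 1.1, 0.5), ("b", "A", "G", 1.1, 0.5),
                        ("c", "A", "G", 1.1, 0.5)])
        stats["INFO"] = [0.95, 0.89, 0.90]
        kept = info_filter(stats)
        assert kept["SNP"].tolist() == ["a", "c"]  # 0.9 itself passes

    def test_missing_info_column_rejected(self):
        with pytest.raises(ValueError):
            info_filter(pd.DataFrame({"SNP": ["x"], "OR": [1.0], "P": [0.5]}))


class TestConcordance:
    def _pair(self, or_, beta):
        scz = _stats([("v", "A", "G", or_, 0.01)])
        iq = scz.drop(columns="OR").assign(BETA=beta)[
            ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "INFO"]
        ]
        return scz, iq

    def test_risk_up_iq_up_is_concordant(self):
        conc, disc = split_by_concordance(*self._pair(1.2, 0.3))
        assert len(conc) == 1 and len(disc) == 0

    def test_risk_down_iq_up_is_discordant(self):
        conc, disc = split_by_concordance(*self._pair(0.8, 0.1))
        assert len(conc) == 0 and len(disc) == 1

    def test_zero_effect_joins_neither(self):
        conc, disc = split_by_concordance(*self._pair(1.0, 0.3))
        assert len(conc) == 0 and len(disc) == 0

    def test_partition_is_disjoint_and_exhaustive(self):
        ds = simulate_genotypes(SimGenConfig(n_individuals=10, n_variants=4000, seed=3))
        scz, iq = simulate_summary_stats(ds.variants, 0.7, null_fraction=0.3, seed=4)
        conc, disc = split_by_concordance(scz, iq)
        nonnull = int((scz["OR"] != 1.0).sum())
        assert len(conc) + len(disc) == nonnull
        assert not set(conc["SNP"]) & set(disc["SNP"])
        # generator ground truth: exactly round(0.7 * nonnull) concordant
        assert len(conc) == round(0.7 * nonnull)

    def test_orientation_mismatch_detected(self):
        scz, iq = self._pair(1.2, 0.3)
        iq.loc[0, ["A1", "A2"]] = ["G", "A"]
        with pytest.raises(ValueError, match="orientation"):
            split_by_concordance(scz, iq)


class TestClumping:
    def test_duplicate_variants_best_p_wins(self):
        rng = np.random.default_rng(5)
        col = rng.integers(0, 3, 200).astype(float)
        ds = make_dataset(np.column_stack([col, col]))
        stats = _stats([("v0", "A", "G", 1.2, 1e-8), ("v1", "A", "G", 1.1, 1e-4)])
        kept = clump_variants(stats, ds)
        assert kept == ["v0"]

    def test_independent_variants_all_retained(self):
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=2000, n_variants=20, ld_rho=0.0, seed=6)
        )
        scz, _ = simulate_summary_stats(ds.variants, 0.5, seed=7)
        kept = clump_variants(scz, ds)
        assert len(kept) == 20

    def test_block_survivors_satisfy_r2_vs_index(self):
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=500, n_variants=30, ld_block_size=10,
                         ld_rho=0.8, seed=8)
        )
        scz, _ = simulate_summary_stats(ds.variants, 0.5, null_fraction=0.0, seed=9)
        kept = clump_variants(scz, ds)
        sel = ds.variants["snp"].isin(kept).to_numpy()
        r2 = pairwise_r2(ds.dosages[:, sel])
        np.fill_diagonal(r2, 0.0)
        assert r2.max() < 0.1


class TestScoring:
    def test_hand_computed_dot_product(self):
        ds = make_dataset(np.array([[0.0, 2.0], [1.0, 1.0]]))
        ds.variants["a1"] = ["A", "A"]
        ds.variants["a2"] = ["G", "G"]
        stats = _stats(
            [("v0", "A", "G", float(np.exp(0.5)), 0.5),
             ("v1", "A", "G", float(np.exp(-0.25)), 0.5)]
        )
        mat = score_individuals(ds, stats, ThresholdGrid((1.0,)))
        assert mat.scores[1.0].tolist() == pytest.approx([-0.5, 0.25])

    def test_all_null_effects_score_zero(self):
        ds = simulate_genotypes(SimGenConfig(n_individuals=20, n_variants=30, seed=10))
        scz, _ = simulate_summary_stats(ds.variants, 0.5, null_fraction=1.0, seed=11)
        mat = score_individuals(ds, scz)
        assert np.all(mat.scores.to_numpy() == 0.0)

    def test_strict_threshold_semantics(self):
        ds = make_dataset(np.array([[1.0], [2.0]]))
        stats = _stats([("v0", "A", "G", 2.0, 0.01)])
        mat = score_individuals(ds, stats, ThresholdGrid((0.001, 1.0)))
        assert mat.n_snps_per_threshold[0.001] == 0
        assert mat.n_snps_per_threshold[1.0] == 1
        assert np.all(mat.scores[0.001].to_numpy() == 0.0)

    def test_monotone_inclusion_and_score_decomposition(self):
        ds = simulate_genotypes(SimGenConfig(n_individuals=80, n_variants=300, seed=12))
        scz, _ = simulate_summary_stats(
            ds.variants, 0.5, null_fraction=0.2, seed=13,
            nonnull_p_range=(1e-8, 0.9),
        )
        h = harmonize_alleles(scz, ds)
        grid = ThresholdGrid()
        mat = score_individuals(ds, h, grid, harmonized=True)
        counts = [mat.n_snps_per_threshold[t] for t in grid.thresholds]
        assert counts == sorted(counts)
        # score difference between adjacent thresholds equals the added SNPs'
        # contribution exactly
        pvals = h["P"].to_numpy()
        eff = np.log(h["OR"].to_numpy())
        dos = ds.dosages[:, h["col_index"].to_numpy()].copy()
        dos[:, h["flip"].to_numpy()] = 2.0 - dos[:, h["flip"].to_numpy()]
        for t1, t2 in zip(grid.thresholds, grid.thresholds[1:]):
            added = (pvals >= t1) & (pvals < t2)
            expected = dos[:, added] @ eff[added]
            delta = mat.scores[t2].to_numpy() - mat.scores[t1].to_numpy()
            assert np.allclose(delta, expected, atol=1e-10)

    def test_matches_naive_per_individual_loop(self):
        ds = simulate_genotypes(
            SimGenConfig(n_individuals=60, n_variants=250, missing_rate=0.01,
                         seed=14)
        )
        scz, _ = simulate_summary_stats(ds.variants, 0.5, seed=15)
        h = harmonize_alleles(scz, ds)
        grid = ThresholdGrid()
        mat = score_individuals(ds, h, grid, harmonized=True)

        eff = np.log(h["OR"].to_numpy())
        pvals = h["P"].to_numpy()
        cols = h["col_index"].to_numpy()
        flip = h["flip"].to_numpy()
        freq = np.nanmean(ds.dosages, axis=0)
        for t in grid.thresholds:
            for i in range(ds.n_individuals):
                s = 0.0
                for k in range(len(h)):
                    if pvals[k] >= t:
                        continue
                    d = ds.dosages[i, cols[k]]
                    if np.isnan(d):
                        d = freq[cols[k]]
                    if flip[k]:
                        d = 2.0 - d
                    s += d * eff[k]
                assert abs(mat.scores[t].iloc[i] - s) < 1e-10

    def test_default_grid_is_the_conventional_eight(self):
        assert ThresholdGrid().thresholds == (
            0.001, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0,
        )
        with pytest.raises(ValueError):
            ThresholdGrid((0.5, 0.1))


class TestRegionRestriction:
    GENE = dict(chrom=22, start_bp=39_946_758, end_bp=40_105_740)

    def _stats_at(self, chrom, bp):
        s = _stats([("v", "A", "G", 1.1, 0.5)])
        s["CHR"] = chrom
        s["BP"] = bp
        return s

    def test_gene_start_retained(self):
        out = restrict_to_region(self._stats_at(22, 39_946_758), **self.GENE)
        assert len(out) == 1

    def test_flank_is_inclusive(self):
        out = restrict_to_region(self._stats_at(22, 39_926_758), **self.GENE)
        assert len(out) == 1  # exactly 20 kb upstream
        out = restrict_to_region(self._stats_at(22, 39_926_757), **self.GENE)
        assert len(out) == 0

    def test_outside_position_removed(self):
        out = restrict_to_region(self._stats_at(22, 39_900_000), **self.GENE)
        assert len(out) == 0

    def test_wrong_chromosome_removed(self):
        out = restrict_to_region(self._stats_at(21, 40_000_000), **self.GENE)
        assert len(out) == 0

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            restrict_to_region(self._stats_at(22, 1), 22, 100, 50)
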