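"""Genotype quality control: sample filters, variant filters, high-quality
SNP set, LD pruning, relatedness exclusion, PCA outlier removal.

The cascade runs in a fixed order — sample QC, variant QC, high-quality-set
construction, LD pruning, relatedness filtering, PCA outliers — matching the
conventional PLINK-era workflow. Defaults: individual missingness > 0.02 or
|heterozygosity deviation| > 0.2 removes a sample; variant MAF < 0.01,
Hardy-Weinberg exact p < 1e-6 or missingness > 0.02 removes a variant; the
high-quality set (HWE p > 0.02, MAF > 0.20, zero missingness) feeds LD
pruning (pairwise r^2 < 0.1 within 200-SNP windows), pi-hat > 0.20
relatedness exclusion, and 20-component PCA with 6-SD outlier removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypeDataset, QCReport


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_aa_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count (the standard genotype-based exact test). Computed with a
    multiplicative recurrence in the heterozygote count, which is stable for
    the sample sizes of genotyping arrays.
    """
    counts = (int(n_aa_hom1), int(n_het), int(n_hom2))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n_hom1, het, n_hom2 = counts
    n = n_hom1 + het + n_hom2
    if n == 0:
        raise ValueError("at least one genotyped individual required")

    n_a = 2 * n_hom1 + het
    n_b = 2 * n - n_a
    rare, common = min(n_a, n_b), max(n_a, n_b)

    # possible heterozygote counts share the parity of the rare allele count
    n_hets = np.arange(rare % 2, rare + 1, 2)
    if n_hets.size == 0:
        return 1.0

    # unnormalized probabilities via the recurrence
    #   P(h+2)/P(h) = 4 * hom_rare(h) * hom_common(h) / ((h+2)(h+1))
    # with hom_rare(h) = (rare - h)/2 and hom_common(h) = (common - h)/2,
    # both fixed by the conditioned allele counts
    probs = np.empty(n_hets.size)
    probs[0] = 1.0
    for i in range(n_hets.size - 1):
        h = int(n_hets[i])
        hom_rare = (rare - h) // 2
        hom_common = (common - h) // 2
        probs[i + 1] = probs[i] * 4.0 * hom_rare * hom_common / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()

    where = np.flatnonzero(n_hets == het)
    if where.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = probs[where[0]]
    # include configurations no more probable than observed (with the usual
    # tiny relative tolerance against floating-point ties)
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_exact_many(dosages: np.ndarray) -> np.ndarray:
    """HWE exact p per variant of a dosage matrix (NaN-aware)."""
    m = dosages.shape[1]
    out = np.ones(m)
    for j in range(m):
        col = dosages[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        out[j] = hwe_exact_test(
            int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
        )
    return out


# ---------------------------------------------------------------------------
# Sample and variant filters
# ---------------------------------------------------------------------------


def _first_reason_removals(
    report: QCReport, axis: str, ids: list[str], reason: str
) -> None:
    seen = (
        report.removed_individual_ids()
        if axis == "individual"
        else report.removed_variant_ids()
    )
    target = (
        report.removed_individuals if axis == "individual" else report.removed_variants
    )
    for i in ids:
        if i not in seen:
            target.append((i, reason))


def heterozygosity_deviation(
    dosages: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """Per-individual (observed het - expected het) / expected het, where the
    expectation is the mean of 2p(1-p) over each individual's non-missing
    calls."""
    het = dosages == 1
    called = ~np.isnan(dosages)
    exp_het_var = 2.0 * freqs * (1.0 - freqs)
    obs = het.sum(axis=1) / np.maximum(called.sum(axis=1), 1)
    exp = (called * exp_het_var).sum(axis=1) / np.maximum(called.sum(axis=1), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = (obs - exp) / exp
    return np.where(exp > 0, dev, 0.0)


def sample_qc(
    dataset: GenotypeDataset,
    miss_thresh: float = 0.02,
    het_thresh: float = 0.2,
    het_snp_set: list[str] | None = None,
    report: QCReport | None = None,
) -> tuple[GenotypeDataset, QCReport]:
    """Remove individuals with high missingness or aberrant heterozygosity.

    Heterozygosity is evaluated on ``het_snp_set`` when given (normally the
    high-quality SNP set), otherwise on all variants. Sex-mismatch checking
    is a logged no-op: no sex chromosomes are modelled.
    """
    if dataset.n_individuals == 0 or dataset.n_variants == 0:
        raise ValueError("empty dataset")
    report = report or QCReport()

    miss = np.isnan(dataset.dosages).mean(axis=1)
    bad_miss = miss > miss_thresh

    if het_snp_set is not None:
        keep = dataset.variants["snp"].isin(het_snp_set).to_numpy()
        sub = dataset.dosages[:, keep]
        freqs = np.nanmean(sub, axis=0) / 2.0
        dev = heterozygosity_deviation(sub, freqs)
    else:
        dev = heterozygosity_deviation(dataset.dosages, dataset.allele_freq())
    bad_het = np.abs(dev) > het_thresh

    iids = dataset.individuals["iid"]
    _first_reason_removals(report, "individual", iids[bad_miss].tolist(), "missingness")
    _first_reason_removals(
        report, "individual", iids[bad_het & ~bad_miss].tolist(), "heterozygosity"
    )
    report.notes.append("sex-mismatch check: not evaluated (no sex chromosomes)")
    keep_ind = ~(bad_miss | bad_het)
    return dataset.subset(individuals=keep_ind), report


def variant_qc(
    dataset: GenotypeDataset,
    maf_thresh: float = 0.01,
    hwe_thresh: float = 1e-6,
    miss_thresh: float = 0.02,
    report: QCReport | None = None,
) -> tuple[GenotypeDataset, QCReport]:
    """Remove variants with low MAF, HWE deviation, or high missingness."""
    if dataset.n_variants == 0:
        raise ValueError("empty dataset")
    report = report or QCReport()

    maf = dataset.maf()
    miss = np.isnan(dataset.dosages).mean(axis=0)
    hwe_p = hwe_exact_many(dataset.dosages)

    snps = dataset.variants["snp"]
    bad_maf = maf < maf_thresh
    bad_hwe = hwe_p < hwe_thresh
    bad_miss = miss > miss_thresh
    _first_reason_removals(report, "variant", snps[bad_maf].tolist(), "maf")
    _first_reason_removals(report, "variant", snps[bad_hwe & ~bad_maf].tolist(), "hwe")
    _first_reason_removals(
        report, "variant", snps[bad_miss & ~bad_maf & ~bad_hwe].tolist(), "missingness"
    )
    keep = ~(bad_maf | bad_hwe | bad_miss)
    return dataset.subset(variants=keep), report


def high_quality_set(
    dataset: GenotypeDataset,
    hwe_thresh: float = 0.02,
    maf_thresh: float = 0.20,
    report: QCReport | None = None,
) -> list[str]:
    """Variants passing the stricter criteria used for pruning, relatedness
    and PCA only: HWE p > 0.02, MAF > 0.20, zero missingness."""
    maf = dataset.maf()
    miss = np.isnan(dataset.dosages).mean(axis=0)
    hwe_p = hwe_exact_many(dataset.dosages)
    keep = (hwe_p > hwe_thresh) & (maf > maf_thresh) & (miss == 0)
    ids = dataset.variants["snp"][keep].tolist()
    if report is not None and not ids:
        report.notes.append("high-quality SNP set is empty")
    return ids


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _imputed_centered(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing calls and center columns (for correlations)."""
    x = dosages.copy()
    means = np.nanmean(x, axis=0)
    nan_r, nan_c = np.where(np.isnan(x))
    x[nan_r, nan_c] = means[nan_c]
    return x - x.mean(axis=0)


def pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (mean-imputed)."""
    x = _imputed_centered(dosages)
    sd = x.std(axis=0)
    sd[sd == 0] = np.inf  # monomorphic: correlation treated as 0
    xs = x / sd
    r = (xs.T @ xs) / x.shape[0]
    return r**2


def ld_prune(
    dataset: GenotypeDataset,
    snp_set: list[str] | None = None,
    r2_thresh: float = 0.1,
    window_size: int = 200,
    step: int = 50,
) -> list[str]:
    """Greedy sliding-window LD pruning (r^2 < ``r2_thresh`` survives).

    Within each ``window_size``-variant window (slid by ``step``), while any
    retained pair correlates at r^2 >= threshold, the member with the lower
    MAF is dropped (ties: the later position). Variants must be
    position-sorted within chromosome.
    """
    if snp_set is not None:
        sel = dataset.variants["snp"].isin(snp_set).to_numpy()
        ds = dataset.subset(variants=sel)
    else:
        ds = dataset
    var = ds.variants
    for _, grp in var.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError("variants must be position-sorted within chromosome")

    maf = ds.maf()
    keep = np.ones(ds.n_variants, dtype=bool)
    for chrom, grp in var.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        start = 0
        while True:
            window = idx[start : start + window_size]
            if window.size >= 2:
                r2 = pairwise_r2(ds.dosages[:, window])
                np.fill_diagonal(r2, 0.0)
                active = keep[window].copy()
                while True:
                    sub = r2[np.ix_(active.nonzero()[0], active.nonzero()[0])]
                    if sub.size == 0 or sub.max() < r2_thresh:
                        break
                    live = active.nonzero()[0]
                    a, b = np.unravel_index(np.argmax(sub), sub.shape)
                    ia, ib = live[a], live[b]
                    ja, jb = window[ia], window[ib]
                    # drop the lower-MAF member; on a tie, the later position
                    ma, mb = maf[ja], maf[jb]
                    if ma < mb or (ma == mb and var.loc[ja, "pos"] > var.loc[jb, "pos"]):
                        active[ia] = False
                    else:
                        active[ib] = False
                keep[window] = keep[window] & active
            if start + window_size >= idx.size:
                break
            start += step
    return var["snp"][keep].tolist()


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------


def pi_hat_matrix(dataset: GenotypeDataset, snp_set: list[str] | None = None) -> np.ndarray:
    """Method-of-moments genome-sharing estimate for every pair.

    Uses the allele-frequency-standardized genotype covariance
    (the off-diagonal of the genomic relationship matrix), whose expectation
    is ~1 for duplicates, ~0.5 for parent-offspring pairs and ~0 for
    unrelated individuals.
    """
    if snp_set is not None:
        sel = dataset.variants["snp"].isin(snp_set).to_numpy()
        ds = dataset.subset(variants=sel)
    else:
        ds = dataset
    p = ds.allele_freq()
    ok = (p > 0) & (p < 1)
    x = _imputed_centered(ds.dosages[:, ok])
    denom = np.sqrt(2.0 * p[ok] * (1.0 - p[ok]))
    xs = x / denom
    grm = (xs @ xs.T) / ok.sum()
    return grm


def relatedness_filter(
    dataset: GenotypeDataset,
    snp_set: list[str] | None = None,
    pi_hat_thresh: float = 0.20,
    seed: int = 0,
    report: QCReport | None = None,
) -> tuple[GenotypeDataset, QCReport]:
    """Remove one random member of every cryptically related pair
    (pi-hat > threshold), iterating until no pair remains."""
    if dataset.n_individuals < 2:
        raise ValueError("need at least two individuals")
    report = report or QCReport()
    rng = np.random.default_rng(seed)

    grm = pi_hat_matrix(dataset, snp_set)
    n = dataset.n_individuals
    active = np.ones(n, dtype=bool)
    while True:
        sub = grm.copy()
        np.fill_diagonal(sub, 0.0)
        sub[~active, :] = 0.0
        sub[:, ~active] = 0.0
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= pi_hat_thresh:
            break
        drop = int(rng.choice([i, j]))
        active[drop] = False
        _first_reason_removals(
            report,
            "individual",
            [dataset.individuals["iid"].iloc[drop]],
            "relatedness",
        )
    return dataset.subset(individuals=active), report


# ---------------------------------------------------------------------------
# PCA outliers
# ---------------------------------------------------------------------------


def _pc_scores(dosages: np.ndarray, n_pcs: int) -> np.ndarray:
    """PC scores (U*S) of the 2p-standardized dosage matrix."""
    p = np.nanmean(dosages, axis=0) / 2.0
    ok = (p > 0) & (p < 1)
    x = _imputed_centered(dosages[:, ok]) / np.sqrt(2.0 * p[ok] * (1.0 - p[ok]))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def pca_outlier_filter(
    dataset: GenotypeDataset,
    snp_set: list[str] | None = None,
    n_pcs: int = 20,
    sd_thresh: float = 6.0,
    report: QCReport | None = None,
) -> tuple[GenotypeDataset, pd.DataFrame, QCReport]:
    """Remove individuals > ``sd_thresh`` SD out on any of the first
    ``n_pcs`` principal components of the pruned high-quality genotypes,
    then recompute the PCs once on the cleaned cohort."""
    report = report or QCReport()
    if snp_set is not None:
        sel = dataset.variants["snp"].isin(snp_set).to_numpy()
        dos = dataset.dosages[:, sel]
    else:
        dos = dataset.dosages
    n_pcs_eff = min(n_pcs, min(dos.shape) - 1)
    if n_pcs_eff < 1:
        raise ValueError("not enough data for PCA")

    scores = _pc_scores(dos, n_pcs_eff)
    z = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    outlier = (np.abs(z) > sd_thresh).any(axis=1)
    _first_reason_removals(
        report,
        "individual",
        dataset.individuals["iid"][outlier].tolist(),
        "pca_outlier",
    )
    cleaned = dataset.subset(individuals=~outlier)

    dos2 = dos[~outlier, :]
    scores2 = _pc_scores(dos2, min(n_pcs_eff, min(dos2.shape) - 1))
    pc_cols = [f"PC{k + 1}" for k in range(scores2.shape[1])]
    pcs = pd.DataFrame(scores2, columns=pc_cols)
    pcs.insert(0, "iid", cleaned.individuals["iid"].to_numpy())
    report.pc_matrix = pcs
    return cleaned, pcs, report


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------


@dataclass
class QCThresholds:
    sample_miss: float = 0.02
    sample_het: float = 0.2
    maf: float = 0.01
    hwe: float = 1e-6
    variant_miss: float = 0.02
    prune_r2: float = 0.1
    prune_window: int = 200
    prune_step: int = 50
    pi_hat: float = 0.20
    pca_sd: float = 6.0
    n_pcs: int = 20


def run_qc(
    dataset: GenotypeDataset,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
) -> tuple[GenotypeDataset, pd.DataFrame, QCReport]:
    """Run the full cascade; returns (clean dataset, PC covariates, report)."""
    th = thresholds or QCThresholds()
    report = QCReport()
    hq0 = high_quality_set(dataset)
    ds, report = sample_qc(
        dataset, th.sample_miss, th.sample_het,
        het_snp_set=hq0 or None, report=report,
    )
    ds, report = variant_qc(ds, th.maf, th.hwe, th.variant_miss, report=report)
    hq = high_quality_set(ds, report=report)
    pruned = ld_prune(ds, hq, th.prune_r2, th.prune_window, th.prune_step)
    report.pruned_snp_set = pruned
    ds, report = relatedness_filter(ds, pruned, th.pi_hat, seed=seed, report=report)
    ds, pcs, report = pca_outlier_filter(
        ds, pruned, th.n_pcs, th.pca_sd, report=report
    )
    return ds, pcs, report
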