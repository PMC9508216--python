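"""Polygenic scores: allele harmonization, info filtering, effect-direction
stratification, LD clumping, and p-value-threshold scoring.

A score at threshold t is the sum over variants with GWAS p < t of the
effect-allele dosage times the effect size (log odds ratio for case-control
traits, beta for quantitative traits). The default threshold grid is the
conventional one: 0.001, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1. Cross-trait
stratification splits variants into those whose effect directions on the
two traits agree (concordant) or oppose (discordant); scoring of each subset
uses the first (case-control) trait's effects and p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypeDataset

DEFAULT_THRESHOLDS = (0.001, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class ThresholdGrid:
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        t = self.thresholds
        if not t or any(not (0 < x <= 1) for x in t):
            raise ValueError("thresholds must lie in (0, 1]")
        if any(a >= b for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")


@dataclass
class PGSMatrix:
    scores: pd.DataFrame  # index iid, one column per threshold
    n_snps_per_threshold: dict[float, int]
    snp_subset_label: str = "all"


def _effect_column(stats: pd.DataFrame) -> str:
    if "OR" in stats.columns:
        return "OR"
    if "BETA" in stats.columns:
        return "BETA"
    raise ValueError("summary statistics need an OR or BETA column")


def log_effects(stats: pd.DataFrame) -> np.ndarray:
    """Additive-scale effects: log(OR) for case-control, beta as-is."""
    col = _effect_column(stats)
    eff = stats[col].to_numpy(dtype=float)
    if col == "OR":
        if (eff <= 0).any():
            raise ValueError("odds ratios must be positive")
        eff = np.log(eff)
    return eff


def harmonize_alleles(
    stats: pd.DataFrame, dataset: GenotypeDataset
) -> pd.DataFrame:
    """Match summary statistics to the genotype panel's allele orientation.

    Returns the overlapping rows of ``stats`` with two added columns:
    ``flip`` (True when the GWAS effect allele is the panel's allele2, so the
    effect-allele dosage is ``2 - dosage``) and ``col_index`` (the variant's
    column in the dosage matrix). Strand-ambiguous palindromic variants
    (A/T, C/G) and allele-incompatible variants are dropped.
    """
    panel = dataset.variants.reset_index(drop=True).copy()
    panel["col_index"] = np.arange(len(panel))
    merged = stats.merge(
        panel[["snp", "a1", "a2", "col_index"]],
        left_on="SNP",
        right_on="snp",
        how="inner",
    )
    if merged.empty:
        raise ValueError("no overlapping variants between stats and genotypes")

    pal = [
        (ea, oa) in _PALINDROMIC
        for ea, oa in zip(merged["A1"], merged["A2"])
    ]
    merged = merged[~np.array(pal)]
    direct = (merged["A1"] == merged["a1"]) & (merged["A2"] == merged["a2"])
    swapped = (merged["A1"] == merged["a2"]) & (merged["A2"] == merged["a1"])
    merged = merged[direct | swapped].copy()
    merged["flip"] = swapped[direct | swapped].to_numpy()
    return merged.drop(columns=["snp", "a1", "a2"]).reset_index(drop=True)


def info_filter(stats: pd.DataFrame, threshold: float = 0.9) -> pd.DataFrame:
    """Drop variants with imputation info score strictly below threshold."""
    if "INFO" not in stats.columns:
        raise ValueError("summary statistics lack an INFO column")
    return stats[stats["INFO"] >= threshold].reset_index(drop=True)


def split_by_concordance(
    scz: pd.DataFrame, iq: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition shared variants by cross-trait effect direction.

    Both tables must be oriented to the same effect allele per variant (an
    orientation mismatch raises). Concordant: sign(log OR) == sign(beta),
    both nonzero. Discordant: opposite signs. Variants with a zero effect in
    either trait join neither subset. Returns the concordant and discordant
    rows of the *SCZ* table — downstream scoring uses the SCZ effects and
    p-values of each subset.
    """
    merged = scz.merge(
        iq[["SNP", "A1", "A2", "BETA"]], on="SNP", suffixes=("", "_iq")
    )
    mismatch = (merged["A1"] != merged["A1_iq"]) | (merged["A2"] != merged["A2_iq"])
    if mismatch.any():
        raise ValueError(
            f"{int(mismatch.sum())} variants have incompatible allele "
            "orientation between the two tables"
        )
    sign_scz = np.sign(np.log(merged["OR"].to_numpy(dtype=float)))
    sign_iq = np.sign(merged["BETA"].to_numpy(dtype=float))
    nonzero = (sign_scz != 0) & (sign_iq != 0)
    conc = nonzero & (sign_scz == sign_iq)
    disc = nonzero & (sign_scz != sign_iq)
    cols = scz.columns
    return (
        merged.loc[conc, cols].reset_index(drop=True),
        merged.loc[disc, cols].reset_index(drop=True),
    )


def clump_variants(
    stats: pd.DataFrame,
    dataset: GenotypeDataset,
    p_field: str = "P",
    r2_thresh: float = 0.1,
    window_kb: float = 250.0,
) -> list[str]:
    """Greedy p-value-aware LD clumping against the cohort's own genotypes.

    Variants are visited by ascending p; each index variant removes every
    not-yet-clumped variant within ``window_kb`` on the same chromosome whose
    genotype r^2 with it is >= ``r2_thresh``. Returns retained variant IDs.
    """
    from .qc import pairwise_r2

    panel = dataset.variants.reset_index(drop=True)
    merged = stats.merge(
        panel.assign(col_index=np.arange(len(panel)))[["snp", "col_index"]],
        left_on="SNP",
        right_on="snp",
    )
    if "BP" not in merged.columns or merged["BP"].isna().any():
        raise ValueError("clumping requires variant positions")
    merged = merged.sort_values(p_field, kind="stable").reset_index(drop=True)

    alive = np.ones(len(merged), dtype=bool)
    retained: list[str] = []
    chrom = merged["CHR"].to_numpy()
    bp = merged["BP"].to_numpy(dtype=float)
    cols = merged["col_index"].to_numpy()
    for i in range(len(merged)):
        if not alive[i]:
            continue
        retained.append(merged["SNP"].iloc[i])
        near = (
            alive
            & (chrom == chrom[i])
            & (np.abs(bp - bp[i]) <= window_kb * 1_000)
        )
        near[i] = False
        if near.any():
            idx = np.flatnonzero(near)
            r2 = pairwise_r2(dataset.dosages[:, np.append(cols[i], cols[idx])])[0, 1:]
            alive[idx[r2 >= r2_thresh]] = False
        alive[i] = False
    return retained


def score_individuals(
    dataset: GenotypeDataset,
    stats: pd.DataFrame,
    grid: ThresholdGrid | None = None,
    subset_label: str = "all",
    harmonized: bool = False,
) -> PGSMatrix:
    """Allele-count x effect-size scores at each p-value threshold.

    ``stats`` is harmonized against the panel first unless ``harmonized``
    (i.e. it already carries ``flip``/``col_index`` columns). Missing dosages
    are mean-imputed with twice the cohort allele frequency; thresholds use
    the strict comparison p < t.
    """
    grid = grid or ThresholdGrid()
    hstats = stats if harmonized else harmonize_alleles(stats, dataset)

    cols = hstats["col_index"].to_numpy()
    eff = log_effects(hstats)
    pvals = hstats["P"].to_numpy(dtype=float)
    flip = hstats["flip"].to_numpy(dtype=bool)

    # orient to the GWAS effect allele first (exact on {0,1,2} calls), then
    # mean-impute missing calls with twice the effect-allele frequency —
    # this order makes scores bit-identical under storage-orientation flips
    dos = dataset.dosages[:, cols].copy()
    dos[:, flip] = 2.0 - dos[:, flip]
    freq = np.nanmean(dos, axis=0)  # mean dosage = 2 * effect-allele freq
    nan_r, nan_c = np.where(np.isnan(dos))
    dos[nan_r, nan_c] = freq[nan_c]

    scores = {}
    n_snps = {}
    for t in grid.thresholds:
        use = pvals < t
        n_snps[t] = int(use.sum())
        if n_snps[t] == 0:
            warnings.warn(f"no SNPs pass threshold {t}; score set to 0")
            scores[t] = np.zeros(dataset.n_individuals)
        else:
            scores[t] = dos[:, use] @ eff[use]
    df = pd.DataFrame(scores, index=dataset.individuals["iid"].to_numpy())
    df.index.name = "iid"
    return PGSMatrix(df, n_snps, subset_label)


def restrict_to_region(
    stats: pd.DataFrame,
    chrom: int | str,
    start_bp: int,
    end_bp: int,
    flank_kb: float = 20.0,
) -> pd.DataFrame:
    """Keep variants inside [start - flank, end + flank] on one chromosome
    (both ends inclusive) — e.g. a gene body plus 20 kb either side."""
    if start_bp > end_bp:
        raise ValueError("inverted interval")
    lo = start_bp - flank_kb * 1_000
    hi = end_bp + flank_kb * 1_000
    keep = (
        (stats["CHR"].astype(str) == str(chrom))
        & (stats["BP"] >= lo)
        & (stats["BP"] <= hi)
    )
    return stats[keep].reset_index(drop=True)
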