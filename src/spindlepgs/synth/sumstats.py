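"""Paired GWAS summary statistics with controlled effect-direction
concordance between a case-control trait (odds ratios; schizophrenia-like)
and a quantitative trait (betas; intelligence-like).

Null variants carry exactly zero effect (OR = 1, beta = 0) and are excluded
from the concordance accounting, since a sign is undefined at zero. Among
non-null variants, exactly ``round(f * n_nonnull)`` are assigned the same
effect direction in both traits; assignment is a seeded permutation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _p_to_se(effect: np.ndarray, p: np.ndarray) -> np.ndarray:
    z = stats.norm.isf(p / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.abs(effect) / z
    se[~np.isfinite(se) | (se == 0)] = 0.1
    return se


def simulate_summary_stats(
    variants: pd.DataFrame,
    concordant_fraction: float,
    effect_sd: float = 0.05,
    null_fraction: float = 0.5,
    seed: int = 0,
    nonnull_p_range: tuple[float, float] = (1e-8, 1e-3),
    info_range: tuple[float, float] = (0.85, 1.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build (SCZ, IQ) summary-statistic tables over the given variants.

    Parameters
    ----------
    variants
        Variant metadata (columns ``snp chrom pos a1 a2``), typically
        ``GenotypeDataset.variants`` — effect alleles are oriented to ``a1``.
    concordant_fraction
        Fraction of non-null variants whose log-OR (SCZ) and beta (IQ) agree
        in sign.
    effect_sd
        SD of non-null log-odds-ratios and beta magnitudes.
    null_fraction
        Fraction of variants with exactly zero effect in both traits.
    nonnull_p_range
        Non-null p-values are log-uniform on this interval; null p-values are
        Uniform(0, 1).
    info_range
        Imputation info scores are uniform on this interval (default spans
        the conventional 0.9 filter so it removes some variants).
    """
    if not (0.0 <= concordant_fraction <= 1.0):
        raise ValueError("concordant_fraction must be in [0, 1]")
    if not (0.0 <= null_fraction <= 1.0):
        raise ValueError("null_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    m = len(variants)
    n_null = int(round(null_fraction * m))
    perm = rng.permutation(m)
    null_idx = perm[:n_null]
    nonnull_idx = perm[n_null:]
    n_nonnull = nonnull_idx.size

    log_or = np.zeros(m)
    beta = np.zeros(m)
    nz = rng.normal(0.0, effect_sd, size=n_nonnull)
    nz[nz == 0.0] = effect_sd  # a.s. unreachable; keeps signs well defined
    log_or[nonnull_idx] = nz

    n_conc = int(round(concordant_fraction * n_nonnull))
    conc_idx = nonnull_idx[:n_conc]  # nonnull_idx is already a random order
    disc_idx = nonnull_idx[n_conc:]
    mag = np.abs(rng.normal(0.0, effect_sd, size=m))
    beta[conc_idx] = np.sign(log_or[conc_idx]) * np.maximum(mag[conc_idx], 1e-12)
    beta[disc_idx] = -np.sign(log_or[disc_idx]) * np.maximum(mag[disc_idx], 1e-12)

    def _pvals() -> np.ndarray:
        p = rng.uniform(0.0, 1.0, size=m)
        lo, hi = nonnull_p_range
        p[nonnull_idx] = 10 ** rng.uniform(
            np.log10(lo), np.log10(hi), size=n_nonnull
        )
        return np.clip(p, np.finfo(float).tiny, 1.0)

    p_scz = _pvals()
    p_iq = _pvals()
    info_scz = rng.uniform(*info_range, size=m)
    info_iq = rng.uniform(*info_range, size=m)

    base = {
        "SNP": variants["snp"].to_numpy(),
        "CHR": variants["chrom"].to_numpy(),
        "BP": variants["pos"].to_numpy(),
        "A1": variants["a1"].to_numpy(),
        "A2": variants["a2"].to_numpy(),
    }
    scz = pd.DataFrame(
        {**base, "OR": np.exp(log_or), "SE": _p_to_se(log_or, p_scz),
         "P": p_scz, "INFO": info_scz}
    )
    iq = pd.DataFrame(
        {**base, "BETA": beta, "SE": _p_to_se(beta, p_iq),
         "P": p_iq, "INFO": info_iq}
    )
    return scz, iq
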