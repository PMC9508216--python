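"""Association of polygenic scores with quantitative phenotypes.

The headline statistic is the *incremental R^2*: the increase in the
ordinary coefficient of determination when the score is added to a linear
base model of sex, age and the first ten genetic principal components. The
threshold scan reports it for every p-value cutoff in the grid (the best one
is flagged, never reported alone); quintile summaries express the same
association as mean phenotype change per score quintile relative to the
lowest quintile. A principal-components regression F-test aggregates a gene
region into a single multi-SNP p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .pgs import PGSMatrix
from .types import AssociationResult, GenotypeDataset, QuintileSummary


def _as_design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != n:
        raise ValueError("covariate rows do not match phenotype length")
    return np.column_stack([np.ones(n), x])


def incremental_r2(
    phenotype: np.ndarray,
    pgs_column: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    threshold: float = np.nan,
    n_snps: int = 0,
) -> AssociationResult:
    """OLS increase in R^2 from adding the score to the covariate model.

    Returns the ordinary (unadjusted) R^2 difference and the two-sided
    t-test p-value of the score coefficient in the full model. A score
    collinear with the base design (e.g. constant) yields incremental R^2 0
    and p 1 rather than an error.
    """
    y = np.asarray(phenotype, dtype=float)
    s = np.asarray(pgs_column, dtype=float)
    n = y.size
    if s.size != n:
        raise ValueError("phenotype and score lengths differ")
    if np.isnan(y).any() or np.isnan(s).any():
        raise ValueError("missing values must be removed before association")
    base = _as_design(covariates, n)
    if n <= base.shape[1] + 2:
        raise ValueError("too few individuals for the covariate model")
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    if np.linalg.matrix_rank(base) < base.shape[1]:
        raise ValueError("rank-deficient covariate design")

    base_fit = sm.OLS(y, base).fit()
    full = np.column_stack([base, s])
    if np.linalg.matrix_rank(full) <= np.linalg.matrix_rank(base):
        return AssociationResult(
            threshold=threshold,
            incremental_r2=0.0,
            coefficient_p=1.0,
            n=n,
            base_r2=float(base_fit.rsquared),
            n_snps=n_snps,
        )
    full_fit = sm.OLS(y, full).fit()
    return AssociationResult(
        threshold=threshold,
        incremental_r2=float(full_fit.rsquared - base_fit.rsquared),
        coefficient_p=float(full_fit.pvalues[-1]),
        n=n,
        base_r2=float(base_fit.rsquared),
        n_snps=n_snps,
    )


def threshold_scan(
    phenotype: np.ndarray,
    pgs_matrix: PGSMatrix,
    covariates: pd.DataFrame | np.ndarray | None,
) -> tuple[list[AssociationResult], AssociationResult]:
    """Incremental R^2 at every threshold; best = max incremental R^2
    (ties broken by smaller coefficient p). All results are returned."""
    results = []
    for t in pgs_matrix.scores.columns:
        res = incremental_r2(
            phenotype,
            pgs_matrix.scores[t].to_numpy(),
            covariates,
            threshold=float(t),
            n_snps=pgs_matrix.n_snps_per_threshold.get(t, 0),
        )
        results.append(res)
    best = max(results, key=lambda r: (r.incremental_r2, -r.coefficient_p))
    return results, best


def quintile_summary(pgs_column: np.ndarray, phenotype: np.ndarray) -> QuintileSummary:
    """Mean phenotype per score quintile, relative to the lowest quintile.

    Individuals are ranked by score (ties broken by stable input order) into
    five groups whose sizes differ by at most one.
    """
    s = np.asarray(pgs_column, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n = s.size
    if n < 5:
        raise ValueError("need at least five individuals for quintiles")
    order = np.argsort(s, kind="stable")
    edges = np.round(np.linspace(0, n, 6)).astype(int)
    means = []
    sizes = []
    boundaries = []
    for g in range(5):
        grp = order[edges[g] : edges[g + 1]]
        means.append(float(y[grp].mean()))
        sizes.append(int(grp.size))
        if g < 4:
            boundaries.append(float(s[order[edges[g + 1] - 1]]))
    changes = tuple(m - means[0] for m in means)
    return QuintileSummary(changes, tuple(boundaries), tuple(sizes))


def gene_based_test(
    dataset: GenotypeDataset,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    variance_kept: float = 0.999,
) -> tuple[float, int]:
    """Multi-SNP gene test by principal-components regression.

    Phenotype and standardized region dosages are residualized on the
    covariates; principal components of the residualized genotype matrix
    retaining >= ``variance_kept`` of its variance enter a joint F-test
    against the residualized phenotype, with denominator degrees of freedom
    n - n_covariates - n_components. Returns (p-value, n_components).

    For a single-variant region this reduces exactly to the covariate-
    adjusted single-SNP F-test (the square of its t statistic).
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if dataset.n_variants == 0:
        raise ValueError("empty gene region")
    base = _as_design(covariates, n)
    k = base.shape[1]

    g = dataset.dosages.copy()
    mu = np.nanmean(g, axis=0)
    nan_r, nan_c = np.where(np.isnan(g))
    g[nan_r, nan_c] = mu[nan_c]
    sd = g.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all region variants are monomorphic")
    g = (g[:, keep] - g[:, keep].mean(axis=0)) / sd[keep]

    # residualize both sides on the covariates
    q, _ = np.linalg.qr(base)
    y_r = y - q @ (q.T @ y)
    g_r = g - q @ (q.T @ g)

    u, svals, _ = np.linalg.svd(g_r, full_matrices=False)
    var = svals**2
    pos = var > var.sum() * 1e-12
    var, u = var[pos], u[:, pos]
    frac = np.cumsum(var) / var.sum()
    n_comp = int(np.searchsorted(frac, variance_kept) + 1)
    n_comp = min(n_comp, var.size)
    df_resid = n - k - n_comp
    if df_resid < 1:
        raise ValueError("retained components exhaust residual degrees of freedom")

    pcs = u[:, :n_comp]  # orthonormal scores
    coef = pcs.T @ y_r
    rss0 = float(y_r @ y_r)
    rss1 = rss0 - float(coef @ coef)
    f = ((rss0 - rss1) / n_comp) / (rss1 / df_resid)
    p = float(sps.f.sf(f, n_comp, df_resid))
    return p, n_comp
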