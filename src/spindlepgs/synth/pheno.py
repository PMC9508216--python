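"""Phenotypes as a linear function of a true genetic score, covariates and
Gaussian noise, calibrated to a target incremental R-squared.

The generative model is

    y = X b + gamma * s_perp + eps,      eps ~ N(0, noise_sd^2)

where ``s_perp`` is the true score residualized on the covariates and
standardized to unit variance, and ``gamma`` is chosen so the *population*
increase in R^2 when the score is added to the covariate-only model equals
``target_incremental_r2``:

    gamma^2 = t * (Var(Xb) + noise_sd^2) / (1 - t).

Residualizing the score first makes the decomposition exact regardless of
score-covariate correlation (e.g. a polygenic score correlated with
population-structure PCs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PhenoModel:
    target_incremental_r2: float = 0.052
    covariate_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_incremental_r2 < 1.0):
            raise ValueError("target_incremental_r2 must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_phenotype(
    true_score: np.ndarray,
    covariates: pd.DataFrame | None,
    model: PhenoModel,
    seed: int = 0,
) -> np.ndarray:
    """Draw one phenotype vector; rows of ``covariates`` align with
    ``true_score``."""
    rng = np.random.default_rng(seed)
    s = np.asarray(true_score, dtype=float)
    n = s.size

    if covariates is not None and len(covariates) != n:
        raise ValueError("true_score and covariates lengths differ")

    if covariates is not None and len(covariates.columns) > 0:
        x = covariates.to_numpy(dtype=float)
        b = np.array(
            [model.covariate_effects.get(c, 0.0) for c in covariates.columns]
        )
        cov_term = x @ b
        design = np.column_stack([np.ones(n), x])
    else:
        cov_term = np.zeros(n)
        design = np.ones((n, 1))

    # residualize and standardize the score
    coef, *_ = np.linalg.lstsq(design, s, rcond=None)
    s_perp = s - design @ coef
    sd = s_perp.std()
    t = model.target_incremental_r2
    if sd == 0:
        if t > 0:
            raise ValueError(
                "true score is collinear with covariates; cannot reach target R2"
            )
        s_perp = np.zeros(n)
    else:
        s_perp = s_perp / sd

    var_rest = float(np.var(cov_term)) + model.noise_sd**2
    if var_rest == 0:
        # noiseless, covariate-free limit: phenotype IS the score (R2 = 1)
        gamma = 1.0 if t > 0 else 0.0
    else:
        gamma = np.sqrt(t * var_rest / (1.0 - t))

    noise = rng.normal(0.0, model.noise_sd, size=n) if model.noise_sd > 0 else 0.0
    return cov_term + gamma * s_perp + noise
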