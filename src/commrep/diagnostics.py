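"""Model diagnostics: dispersion, collinearity, stability, coding reliability."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.outliers_influence import variance_inflation_factor

from commrep.glmm import GLMMFit, ModelSpec, fit_poisson_glmm


def overdispersion(fit: GLMMFit) -> float:
    """Dispersion parameter: sum of squared Pearson residuals / residual df.

    Residual df = n_obs - n_fixed_params - n_variance_params.  Values near
    1 indicate a well-specified Poisson model; values above 1 indicate
    overdispersion.
    """
    resid_df = fit.n_obs - fit.n_fixed - 1
    if resid_df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    return float(np.sum(fit.pearson_residuals**2) / resid_df)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors of a fixed-effects design.

    ``design`` holds the non-intercept main-effect columns only (the
    quadratic age term is excluded by convention); VIF_j = 1 / (1 - R^2_j)
    from regressing column j on the remaining columns plus an intercept.
    Rank-deficient designs yield infinite VIFs.
    """
    if design.shape[1] < 2:
        raise ValueError("need at least two predictor columns")
    X = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
    with np.errstate(divide="ignore"):
        values = [
            variance_inflation_factor(X, j + 1) for j in range(design.shape[1])
        ]
    return pd.Series(values, index=list(design.columns), name="vif")


def main_effects_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Main-effects-only design for the collinearity check (no age^2)."""
    cols = [t for t in spec.fixed_terms if t != "age_squared"]
    return data.loc[:, cols]


def stability_by_group_deletion(
    spec: ModelSpec, data: pd.DataFrame
) -> pd.DataFrame:
    """Case-wise deletion of random-effect levels: coefficient ranges.

    Refits the model once per excluded group level and reports, per fixed
    coefficient, the full-data estimate, the min and max across deletions,
    and whether any deletion flips the sign.  Failed refits are recorded
    and skipped.
    """
    groups = data[spec.random_intercept].astype(str).unique()
    if len(groups) < 3:
        raise ValueError("need at least 3 group levels for stability checks")
    full = fit_poisson_glmm(spec, data, se=False)
    estimates = {}
    failures = []
    for g in groups:
        sub = data[data[spec.random_intercept].astype(str) != g]
        try:
            fit_g = fit_poisson_glmm(spec, sub, se=False)
        except Exception:
            failures.append(g)
            continue
        if not fit_g.converged:
            failures.append(g)
            continue
        estimates[g] = fit_g.coefficients
    if not estimates:
        raise ValueError("every leave-one-group-out refit failed")
    mat = np.array(list(estimates.values()))
    table = pd.DataFrame(
        {
            "estimate": full.coefficients,
            "min": mat.min(axis=0),
            "max": mat.max(axis=0),
        },
        index=list(full.terms),
    )
    table["sign_flip"] = np.sign(table["min"]) * np.sign(table["max"]) < 0
    table.attrs["failed_deletions"] = failures
    return table


def cohen_kappa(codes_a: Sequence, codes_b: Sequence) -> float:
    """Cohen's kappa chance-corrected agreement between two coders.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from the
    product of the two coders' marginal label frequencies.  Raises on
    length mismatch or degenerate marginals (p_e = 1, i.e. both coders
    use a single identical label).
    """
    a, b = np.asarray(codes_a), np.asarray(codes_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("code vectors must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least two coded items")
    labels = np.union1d(a, b)
    p_a = np.array([(a == l).mean() for l in labels])
    p_b = np.array([(b == l).mean() for l in labels])
    if np.isclose(float(p_a @ p_b), 1.0):
        raise ValueError("degenerate marginals: expected agreement is 1")
    return float(cohen_kappa_score(a, b))
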