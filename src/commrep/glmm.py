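"""Poisson mixed models of repertoire size and social-goal diversity.

The models are log-link Poisson GLMMs with a single Gaussian random
intercept for the sampling group (zoo or field site):

    y_i | b_g ~ Poisson(exp(x_i' beta + b_g)),   b_g ~ N(0, sigma^2).

Fixed effects follow the study design: the test predictors are age, age
squared, research setting (wild vs captive) and species (Sumatran vs
Bornean); the control predictors are sex and observation effort (log- then
z-transformed).  Estimation is maximum likelihood with the random intercept
integrated out per group by the Laplace approximation (default) or k-point
adaptive Gauss-Hermite quadrature (k = 1 reproduces Laplace exactly), so
likelihood-ratio tests on fixed effects are valid.  The combined effect of
the four test predictors is assessed by a full-vs-null LRT (df = 4, the
null model keeping only the controls and the random intercept), and
per-term tests are single-term-deletion LRTs.

The marginal likelihood of one group is a one-dimensional integral

    L_g = ∫ [ prod_{i in g} Poisson(y_i; exp(eta_i + b)) ] phi(b; 0, sigma^2) db,

maximised over (beta, log sigma) by bounded quasi-Newton with starting
values from the plain Poisson GLM.  Because the Poisson log-likelihood in b
is concave, the inner mode is found by a safeguarded 1-D Newton iteration,
vectorised over groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm

from commrep.records import IndividualProfile
from commrep.repertoires import Repertoire

TEST_PREDICTORS = ("age", "age_squared", "setting_wild", "species_sumatran")
CONTROL_PREDICTORS = ("sex_male", "log_z_effort")

_SIGMA_FLOOR = 1e-6      # lower bound for sigma in the optimiser
_SINGULAR_SIGMA = 1e-3   # below this the fit is reported as singular


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one repertoire-size or social-goal model."""

    response: str = "repertoire_size"      # or "goal_count"
    scope: str = "other"
    test_predictors: tuple[str, ...] = TEST_PREDICTORS
    control_predictors: tuple[str, ...] = CONTROL_PREDICTORS
    random_intercept: str = "group_id"
    estimation: str = "laplace"            # "laplace" or "agq:<k>"
    center_age: bool = False               # square centred age instead of raw

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        return self.test_predictors + self.control_predictors

    @property
    def nagq(self) -> int:
        if self.estimation == "laplace":
            return 1
        if self.estimation.startswith("agq:"):
            k = int(self.estimation.split(":", 1)[1])
            if k < 1:
                raise ValueError("quadrature order must be >= 1")
            return k
        raise ValueError(f"unknown estimation method {self.estimation!r}")

    def null_spec(self) -> "ModelSpec":
        """Null model: control predictors and random intercept only."""
        return replace(self, test_predictors=())


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of two nested fits."""

    chi_square: float
    df: int
    p_value: float
    term: str | None = None


@dataclass
class GLMMFit:
    """A fitted Poisson mixed model (log link, one random intercept)."""

    terms: tuple[str, ...]              # design column names incl. intercept
    coefficients: np.ndarray            # on the log link scale
    std_errors: np.ndarray
    sigma: float                        # random-intercept SD
    log_likelihood: float
    converged: bool
    singular: bool                      # variance component at the boundary
    n_obs: int
    n_groups: int
    nagq: int
    group_labels: tuple[str, ...] = ()
    random_effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    fitted_means: np.ndarray = field(default_factory=lambda: np.empty(0))
    pearson_residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    spec: ModelSpec | None = None

    @property
    def random_intercept_variance(self) -> float:
        return 0.0 if self.singular else self.sigma**2

    @property
    def n_fixed(self) -> int:
        return len(self.terms)

    @property
    def n_params(self) -> int:
        return self.n_fixed + 1  # + variance component

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.std_errors[self.terms.index(term)])

    def wald_interval(self, term: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        est, se = self.coef(term), self.se(term)
        return est - z * se, est + z * se

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.coefficients, "se": self.std_errors},
            index=list(self.terms),
        )

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coefficients": self.coefficients.tolist(),
            "std_errors": self.std_errors.tolist(),
            "random_intercept_variance": self.random_intercept_variance,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "singular": self.singular,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "nagq": self.nagq,
        }


def log_z_transform(effort: Sequence[float]) -> np.ndarray:
    """Natural log followed by z-scoring (mean 0, SD 1 with n-1 denominator).

    Computed on the analysis subset at hand; raises on non-positive effort
    or zero variance.
    """
    effort = np.asarray(effort, dtype=float)
    if effort.size < 2:
        raise ValueError("need at least two effort values to standardise")
    if (effort <= 0).any():
        raise ValueError("effort values must be positive")
    logged = np.log(effort)
    sd = logged.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in log effort")
    return (logged - logged.mean()) / sd


def build_model_frame(
    repertoires: Sequence[Repertoire],
    profiles: Sequence[IndividualProfile],
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Analysis table for one model: response, predictors and group id.

    Reference levels follow alphabetical (treatment) coding: captive for
    setting, Bornean for species, female for sex — so ``setting_wild`` is
    the wild-minus-captive contrast.  Effort is log-z-transformed on this
    subset.  ``age_squared`` is the square of raw age unless
    ``spec.center_age`` is set, in which case age is mean-centred first.
    """
    spec = spec or ModelSpec()
    prof = {p.individual_id: p for p in profiles}
    rows = []
    for rep in repertoires:
        p = prof[rep.individual_id]
        rows.append(
            {
                "individual_id": rep.individual_id,
                "repertoire_size": rep.size,
                "goal_count": rep.goal_count,
                "age": p.age_years,
                "setting_wild": float(p.setting == "wild"),
                "species_sumatran": float(p.species == "sumatran"),
                "sex_male": float(p.sex == "male"),
                "effort": rep.effort,
                "group_id": p.group_id,
            }
        )
    frame = pd.DataFrame(rows)
    age = frame["age"] - frame["age"].mean() if spec.center_age else frame["age"]
    frame["age_squared"] = age**2
    frame["log_z_effort"] = log_z_transform(frame["effort"])
    return frame


def _design(spec: ModelSpec, data: pd.DataFrame):
    terms = ("intercept",) + spec.fixed_terms
    X = np.column_stack(
        [np.ones(len(data))] + [data[t].to_numpy(float) for t in spec.fixed_terms]
    )
    y = data[spec.response].to_numpy(float)
    groups = data[spec.random_intercept].astype(str).to_numpy()
    return terms, X, y, groups


def _group_modes(S, T, sigma2, n_iter=50, tol=1e-10):
    """Conditional modes b_g of the random intercepts, vectorised over groups.

    Solves S - exp(b) T - b / sigma2 = 0 per group by damped Newton; the
    objective is strictly concave in b so the iteration is safe.
    """
    b = np.zeros_like(S)
    for _ in range(n_iter):
        eb = np.exp(b)
        grad = S - eb * T - b / sigma2
        hess = -eb * T - 1.0 / sigma2
        step = grad / hess
        # trust step length to keep exp() in range
        step = np.clip(step, -5.0, 5.0)
        b = b - step
        if np.max(np.abs(grad)) < tol:
            break
    return b


def _marginal_loglik(params, X, y, group_idx, n_groups, nagq, gh_nodes, gh_weights):
    """Laplace / adaptive-GH marginal log-likelihood at (beta, log sigma)."""
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    sigma2 = sigma * sigma
    eta0 = X @ beta
    exp_eta0 = np.exp(eta0)
    S = np.bincount(group_idx, weights=y, minlength=n_groups)
    T = np.bincount(group_idx, weights=exp_eta0, minlength=n_groups)
    yeta = np.bincount(group_idx, weights=y * eta0, minlength=n_groups)
    const = -np.sum(special.gammaln(y + 1.0))

    b_hat = _group_modes(S, T, sigma2)
    # f_g(b) = yeta_g + S_g b - T_g e^b - b^2/(2 sigma2) - 0.5 log(2 pi sigma2)
    def f(b):
        return (
            yeta + S * b - T * np.exp(b) - b**2 / (2 * sigma2)
            - 0.5 * np.log(2 * np.pi * sigma2)
        )

    neg_fpp = T * np.exp(b_hat) + 1.0 / sigma2   # -f''(b_hat) > 0
    if nagq == 1:
        ll_groups = f(b_hat) + 0.5 * np.log(2 * np.pi) - 0.5 * np.log(neg_fpp)
    else:
        tau = 1.0 / np.sqrt(neg_fpp)
        nodes = np.sqrt(2.0) * tau[:, None] * gh_nodes[None, :] + b_hat[:, None]
        log_terms = (
            yeta[:, None] + S[:, None] * nodes - T[:, None] * np.exp(nodes)
            - nodes**2 / (2 * sigma2)
            - 0.5 * np.log(2 * np.pi * sigma2)
            + gh_nodes[None, :] ** 2
            + np.log(gh_weights[None, :])
        )
        m = log_terms.max(axis=1)
        ll_groups = (
            m + np.log(np.exp(log_terms - m[:, None]).sum(axis=1))
            + 0.5 * np.log(2.0) + np.log(tau)
        )
    return float(ll_groups.sum() + const), b_hat


def fit_poisson_glmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    se: bool = True,
) -> GLMMFit:
    """Maximum-likelihood fit of the Poisson random-intercept model.

    Starting values come from the plain Poisson GLM (IRLS) with sigma
    initialised at 0.5; the optimiser is L-BFGS-B on (beta, log sigma) with
    sigma bounded away from zero only by a tiny floor, so variance
    components can collapse to the boundary — such fits are flagged
    ``singular`` and reported with variance 0.  Standard errors are
    observed-information Wald SEs for the fixed effects at the optimum.
    Deterministic given the data.
    """
    terms, X, y, groups = _design(spec, data)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in the model frame")
    labels, group_idx = np.unique(groups, return_inverse=True)
    n_groups = len(labels)
    nagq = spec.nagq
    gh_nodes, gh_weights = np.polynomial.hermite.hermgauss(max(nagq, 1))

    with warnings.catch_warnings():
        # the GLM is only a source of starting values; separation warnings
        # on degenerate starts are handled by the mixed-model optimiser
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    x0 = np.append(glm.params, np.log(0.5))

    def neg_ll(params):
        ll, _ = _marginal_loglik(
            params, X, y, group_idx, n_groups, nagq, gh_nodes, gh_weights
        )
        return -ll

    bounds = [(None, None)] * X.shape[1] + [(np.log(_SIGMA_FLOOR), 5.0)]
    res = optimize.minimize(
        neg_ll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    params = res.x
    ll, b_hat = _marginal_loglik(
        params, X, y, group_idx, n_groups, nagq, gh_nodes, gh_weights
    )
    beta, sigma = params[:-1], float(np.exp(params[-1]))
    singular = sigma < _SINGULAR_SIGMA

    if se:
        std_errors = _wald_se(params, neg_ll, X.shape[1])
    else:
        std_errors = np.full(X.shape[1], np.nan)

    eta = X @ beta + b_hat[group_idx]
    mu = np.exp(eta)
    pearson = (y - mu) / np.sqrt(mu)
    return GLMMFit(
        terms=terms,
        coefficients=beta,
        std_errors=std_errors,
        sigma=sigma,
        log_likelihood=ll,
        converged=bool(res.success),
        singular=singular,
        n_obs=len(y),
        n_groups=n_groups,
        nagq=nagq,
        group_labels=tuple(labels),
        random_effects=b_hat,
        fitted_means=mu,
        pearson_residuals=pearson,
        spec=spec,
    )


def _wald_se(params, neg_ll, n_fixed, rel_step=1e-5):
    """SEs from the inverse observed information of the fixed-effect block.

    The Hessian of the negative marginal log-likelihood is taken over the
    fixed effects with the variance parameter held at its MLE (the usual
    mixed-model convention), by central finite differences.
    """
    p = n_fixed
    h = rel_step * np.maximum(np.abs(params[:p]), 1.0)
    H = np.empty((p, p))
    f0 = neg_ll(params)
    for a in range(p):
        for b in range(a, p):
            x = params.copy()
            if a == b:
                x[a] = params[a] + h[a]
                fp = neg_ll(x)
                x[a] = params[a] - h[a]
                fm = neg_ll(x)
                H[a, a] = (fp - 2 * f0 + fm) / h[a] ** 2
            else:
                x[a], x[b] = params[a] + h[a], params[b] + h[b]
                fpp = neg_ll(x)
                x[b] = params[b] - h[b]
                fpm = neg_ll(x)
                x[a] = params[a] - h[a]
                fmm = neg_ll(x)
                x[b] = params[b] + h[b]
                fmp = neg_ll(x)
                H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * h[a] * h[b])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se


def lrt(full: GLMMFit, null: GLMMFit) -> LRTResult:
    """Likelihood-ratio test of two nested fits on the same data.

    chi^2 = 2 (l_full - l_null), df = difference in parameter count,
    p from the upper tail of the chi-square distribution.
    """
    if full.n_obs != null.n_obs:
        raise ValueError("fits compare different data (n_obs differs)")
    if not set(null.terms) <= set(full.terms):
        raise ValueError("null model is not nested in the full model")
    df = full.n_params - null.n_params
    if df < 1:
        raise ValueError("full model must have more parameters than the null")
    chi2 = max(2.0 * (full.log_likelihood - null.log_likelihood), 0.0)
    return LRTResult(chi_square=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))


def full_null_lrt(spec: ModelSpec, data: pd.DataFrame) -> tuple[LRTResult, GLMMFit, GLMMFit]:
    """Combined test of the four test predictors (df = 4 by design)."""
    full = fit_poisson_glmm(spec, data, se=False)
    null = fit_poisson_glmm(spec.null_spec(), data, se=False)
    return lrt(full, null), full, null


def drop1_lrt(
    spec: ModelSpec, data: pd.DataFrame, full: GLMMFit | None = None
) -> list[LRTResult]:
    """Single-term-deletion LRTs for every fixed term (1 df each)."""
    if full is None:
        full = fit_poisson_glmm(spec, data, se=False)
    if not full.converged:
        raise ValueError("full model did not converge; drop1 is not meaningful")
    results = []
    for term in spec.fixed_terms:
        reduced = replace(
            spec,
            test_predictors=tuple(t for t in spec.test_predictors if t != term),
            control_predictors=tuple(
                t for t in spec.control_predictors if t != term
            ),
        )
        fit_r = fit_poisson_glmm(reduced, data, se=False)
        r = lrt(full, fit_r)
        results.append(replace(r, term=term))
    return results
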