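"""Weibull proportional-hazards time-to-healing model.

The cohort model needs a per-day probability of healing that depends on the
treatment arm and on ulcer covariates.  That probability comes from a
Weibull regression on the trial data, fitted here by maximum likelihood in
the proportional-hazards (rate) parameterisation

    h(t | x) = gamma * lambda * t**(gamma - 1),   lambda = exp(beta0 + x @ beta)
    S(t | x) = exp(-lambda * t**gamma)

with right-censoring: amputation, death and end of follow-up all censor the
healing time.  Uncertainty propagates into the probabilistic analysis via
the Cholesky factor of the coefficient covariance matrix, so parameter
draws preserve the estimated correlations; the shape is handled on the log
scale (log gamma and the log rate are treated as jointly normal).

Note for readers used to accelerated-failure-time (AFT) output (e.g. from
``lifelines``): an AFT fit with scale ``exp(x @ b_aft)`` and shape ``rho``
maps onto this parameterisation as ``gamma = rho`` and
``beta = -rho * b_aft``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .trial import TrialDataset

__all__ = [
    "COEF_NAMES",
    "WeibullFit",
    "CholeskyFactor",
    "CovariateProfile",
    "fit_weibull_ph",
    "compare_aic",
    "cholesky",
    "sample_coefficients",
    "daily_healing_prob",
    "linear_predictor",
]

logger = logging.getLogger(__name__)

#: regression coefficients, in design-matrix order (constant first)
COEF_NAMES = (
    "const",
    "ulcer_age_days",
    "ulcer_area_cm2",
    "infected",
    "low_dose",
    "high_dose",
)


@dataclass(frozen=True)
class WeibullFit:
    """A fitted Weibull (or exponential) healing model.

    ``vcov`` is over the internal parameter vector ``(log gamma, *coeffs)``
    (``coeffs`` only for the exponential family, where the shape is fixed
    at 1 and not estimated).
    """

    shape: float
    coeffs: pd.Series
    vcov: np.ndarray
    loglik: float
    n_events: int
    n_censored: int
    family: str = "weibull"

    @property
    def n_params(self) -> int:
        return len(self.coeffs) + (1 if self.family == "weibull" else 0)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def param_names(self) -> tuple[str, ...]:
        base = tuple(self.coeffs.index)
        return (("log_shape",) + base) if self.family == "weibull" else base

    @property
    def params(self) -> np.ndarray:
        """Internal parameter vector matching ``vcov``'s ordering."""
        if self.family == "weibull":
            return np.concatenate([[math.log(self.shape)],
                                   self.coeffs.to_numpy()])
        return self.coeffs.to_numpy()

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))
        return pd.DataFrame(
            {"estimate": self.params, "se": se}, index=self.param_names
        )


@dataclass(frozen=True)
class CholeskyFactor:
    """Lower-triangular L with L @ L.T equal to a fit's covariance matrix."""

    L: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.L, dtype=float)
        if L.ndim != 2 or L.shape[0] != L.shape[1]:
            raise ValueError("Cholesky factor must be square")
        if not np.allclose(L, np.tril(L)):
            raise ValueError("Cholesky factor must be lower triangular")


@dataclass(frozen=True)
class CovariateProfile:
    """One patient profile: ulcer covariates plus exactly one arm."""

    ulcer_age_days: float
    ulcer_area_cm2: float
    infected: float
    arm: str = "standard"

    def __post_init__(self) -> None:
        if self.arm not in ("standard", "low_dose", "high_dose"):
            raise ValueError(f"unknown arm {self.arm!r}")

    def design_row(self) -> np.ndarray:
        return np.array(
            [
                1.0,
                self.ulcer_age_days,
                self.ulcer_area_cm2,
                self.infected,
                1.0 if self.arm == "low_dose" else 0.0,
                1.0 if self.arm == "high_dose" else 0.0,
            ]
        )

    def with_arm(self, arm: str) -> "CovariateProfile":
        return CovariateProfile(self.ulcer_age_days, self.ulcer_area_cm2,
                                self.infected, arm)


def _design(dataset: TrialDataset, covariates: tuple[str, ...]
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    frame = dataset.to_frame()
    if len(frame) == 0:
        raise ValueError("empty dataset")
    columns = {
        "ulcer_age_days": lambda f: f["ulcer_age_days"].to_numpy(float),
        "ulcer_area_cm2": lambda f: f["ulcer_area_cm2"].to_numpy(float),
        "infected": lambda f: f["infected"].to_numpy(float),
        "low_dose": lambda f: (f["arm"] == "low_dose").to_numpy(float),
        "high_dose": lambda f: (f["arm"] == "high_dose").to_numpy(float),
    }
    unknown = [c for c in covariates if c not in columns]
    if unknown:
        raise ValueError(f"unknown covariates {unknown!r}")
    X = np.column_stack(
        [np.ones(len(frame))] + [columns[c](frame) for c in covariates]
    )
    t = frame["time_days"].to_numpy(float)
    d = (frame["event"] == "healed").to_numpy(float)
    if np.any(t <= 0):
        raise ValueError("non-positive event/censoring times")
    return X, t, d


def _negloglik_weibull(params: np.ndarray, X: np.ndarray, t: np.ndarray,
                       d: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient in (log gamma, beta)."""
    a, beta = params[0], params[1:]
    gamma = math.exp(a)
    eta = X @ beta
    logt = np.log(t)
    tg = np.exp(gamma * logt)          # t**gamma
    cumhaz = np.exp(eta) * tg
    ll = float(np.sum(d * (a + eta + (gamma - 1.0) * logt)) - np.sum(cumhaz))
    grad_beta = X.T @ (d - cumhaz)
    grad_a = float(np.sum(d * (1.0 + gamma * logt)) - np.sum(cumhaz * gamma * logt))
    grad = np.concatenate([[grad_a], grad_beta])
    return -ll, -grad


def _negloglik_exponential(beta: np.ndarray, X: np.ndarray, t: np.ndarray,
                           d: np.ndarray) -> tuple[float, np.ndarray]:
    eta = X @ beta
    cumhaz = np.exp(eta) * t
    ll = float(np.sum(d * eta) - np.sum(cumhaz))
    return -ll, -(X.T @ (d - cumhaz))


def _numeric_hessian(grad_fn, params: np.ndarray) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    k = len(params)
    H = np.zeros((k, k))
    for j in range(k):
        h = 1e-5 * max(1.0, abs(params[j]))
        up, dn = params.copy(), params.copy()
        up[j] += h
        dn[j] -= h
        H[:, j] = (grad_fn(up) - grad_fn(dn)) / (2 * h)
    return 0.5 * (H + H.T)


def fit_weibull_ph(dataset: TrialDataset, family: str = "weibull",
                   covariates: tuple[str, ...] = COEF_NAMES[1:]) -> WeibullFit:
    """Fit the healing model by maximum likelihood under right-censoring.

    Amputation, death and administrative censoring all censor the healing
    time.  The covariance matrix is the inverse of the observed information
    (numerically differentiated analytic gradient).  ``covariates`` selects
    the regression terms (default: all five); pass ``()`` for an
    intercept-only model.

    Raises
    ------
    ValueError
        If there are no healing events, non-positive times, or the
        optimiser fails to converge.
    """
    if family not in ("weibull", "exponential"):
        raise ValueError(f"unknown family {family!r}")
    X, t, d = _design(dataset, tuple(covariates))
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError("no healing events in dataset")

    # standardise the non-constant columns for a well-conditioned
    # optimisation, then map estimates and vcov back to the raw scale
    m = X.mean(axis=0)
    s = X.std(axis=0)
    m[0], s[0] = 0.0, 1.0
    s[s == 0] = 1.0
    Xs = (X - m) / s

    # exponential intercept start: log(rate) = log(events / exposure)
    beta0 = math.log(n_events / float(t.sum()))
    n_beta = X.shape[1]
    if family == "weibull":
        x0 = np.concatenate([[0.0], [beta0], np.zeros(n_beta - 1)])
        fun = lambda p: _negloglik_weibull(p, Xs, t, d)
        offset = 1
    else:
        x0 = np.concatenate([[beta0], np.zeros(n_beta - 1)])
        fun = lambda p: _negloglik_exponential(p, Xs, t, d)
        offset = 0

    res = optimize.minimize(fun, x0, jac=True, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-9})
    grad_inf = float(np.linalg.norm(res.jac, np.inf))
    if grad_inf > 1e-4 * max(1.0, n_events):
        raise ValueError(
            "Weibull fit did not converge: "
            f"{res.message} after {res.nit} iterations "
            f"(|grad|_inf={grad_inf:.3g})"
        )

    grad_only = lambda p: fun(p)[1]
    H = _numeric_hessian(grad_only, res.x)
    try:
        vcov_std = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov_std = np.linalg.pinv(H)

    # back-transform: beta_j = beta_std_j / s_j,
    # beta_0 = beta_std_0 - sum_j beta_std_j m_j / s_j
    k = len(res.x)
    J = np.eye(k)
    for j in range(1, n_beta):
        J[offset, offset + j] = -m[j] / s[j]
        J[offset + j, offset + j] = 1.0 / s[j]
    params = J @ res.x
    vcov = J @ vcov_std @ J.T

    names = ("const",) + tuple(covariates)
    if family == "weibull":
        shape = math.exp(params[0])
        coeffs = pd.Series(params[1:], index=names)
    else:
        shape = 1.0
        coeffs = pd.Series(params, index=names)
    return WeibullFit(
        shape=shape,
        coeffs=coeffs,
        vcov=vcov,
        loglik=-float(res.fun),
        n_events=n_events,
        n_censored=len(t) - n_events,
        family=family,
    )


def compare_aic(dataset: TrialDataset,
                families: Iterable[str] = ("exponential", "weibull"),
                ) -> pd.DataFrame:
    """Fit each candidate family and rank by AIC (ties favour fewer params)."""
    rows = []
    for fam in families:
        fit = fit_weibull_ph(dataset, family=fam)
        rows.append({"family": fam, "k": fit.n_params,
                     "loglik": fit.loglik, "aic": fit.aic})
    table = pd.DataFrame(rows).sort_values(
        ["aic", "k"], kind="stable"
    ).reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table


def cholesky(fit_or_vcov: WeibullFit | np.ndarray,
             max_jitter: float = 1e-10) -> CholeskyFactor:
    """Lower-triangular factor of a (near-)positive-semidefinite covariance.

    Semidefinite inputs (common for pilot-scale data) are handled by adding
    a diagonal jitter of at most ``max_jitter``, with a logged warning.
    """
    vcov = fit_or_vcov.vcov if isinstance(fit_or_vcov, WeibullFit) else fit_or_vcov
    vcov = np.asarray(vcov, dtype=float)
    vcov = 0.5 * (vcov + vcov.T)
    if np.any(np.diag(vcov) < -max_jitter):
        raise ValueError("not a covariance matrix: negative diagonal")
    if not vcov.any():          # exactly degenerate: factor is zero
        return CholeskyFactor(L=np.zeros_like(vcov))
    try:
        return CholeskyFactor(L=np.linalg.cholesky(vcov))
    except np.linalg.LinAlgError:
        pass
    try:
        L = np.linalg.cholesky(vcov + max_jitter * np.eye(len(vcov)))
    except np.linalg.LinAlgError:
        raise ValueError(
            "not a covariance matrix: Cholesky failed even with "
            f"jitter {max_jitter:.1e}"
        )
    logger.warning(
        "covariance matrix not positive definite; added diagonal jitter %.1e",
        max_jitter,
    )
    return CholeskyFactor(L=L)


def sample_coefficients(fit: WeibullFit, L: CholeskyFactor, n_draws: int,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Correlated multivariate-normal draws of the internal parameters.

    Each row is ``mean + L @ z`` with ``z`` standard normal; the first
    column is log shape (for the Weibull family), so the shape and rate are
    log-normal on the natural scale.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    z = rng.standard_normal((n_draws, len(fit.params)))
    return fit.params + z @ np.asarray(L.L).T


def linear_predictor(coeffs: Sequence[float] | pd.Series,
                     profile: CovariateProfile) -> float:
    """eta = beta0 + x @ beta for one covariate profile."""
    return float(np.asarray(coeffs, dtype=float) @ profile.design_row())


def daily_healing_prob(shape: float, rate: float,
                       day: int | np.ndarray) -> float | np.ndarray:
    """Probability of healing during cycle ``day`` (completed days -> day+1).

    With ``S(t) = exp(-rate * t**shape)`` this is ``1 - S(day+1)/S(day)``;
    constant in ``day`` when shape == 1.
    """
    day_arr = np.asarray(day, dtype=float)
    if np.any(day_arr < 0):
        raise ValueError("day must be >= 0")
    p = 1.0 - np.exp(-rate * ((day_arr + 1.0) ** shape - day_arr ** shape))
    if np.isscalar(day) or day_arr.ndim == 0:
        return float(p)
    return p
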