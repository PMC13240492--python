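"""Cost-effectiveness analysis: base case, PSA, CEAC and subgroups.

Three strategies are compared for an open diabetic foot ulcer: standard
care alone, and low- or high-dose shockwave therapy added to standard care.
Each strategy differs only in its healing hazard (through the treatment
coefficient of the survival model) and its one-off intervention cost.

The deterministic analysis runs the cohort model at point estimates and
applies the dominance decision rule (a strategy dominates when it yields
strictly more QALYs at strictly lower cost; an ICER is only computed when
neither strategy dominates).  The probabilistic analysis re-runs the
cohort model for each of ``n_iter`` joint parameter draws — survival
coefficients correlated through the Cholesky factor of the fit covariance,
everything else independent — and summarises decision uncertainty as
cost-effectiveness acceptability curves (CEAC) and the incremental
cost-effectiveness plane.  The subgroup analysis fixes the ulcer
covariates at each profile of a size/duration/infection grid and reports
incremental net monetary benefit (NMB) versus standard care at a
willingness-to-pay threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distributions import ParameterDistributions
from .markov import (DailyTransitionParams, StateCosts, StateUtilities,
                     run_cohort, run_cohort_batch)
from .survival import (CovariateProfile, WeibullFit, cholesky,
                       daily_healing_prob, linear_predictor,
                       sample_coefficients)

__all__ = [
    "STRATEGIES",
    "DEFAULT_THRESHOLD",
    "DEFAULT_THRESHOLD_GRID",
    "DecisionModel",
    "CEResult",
    "PsaResult",
    "SubgroupProfile",
    "nmb",
    "dominance",
    "incremental_table",
    "deterministic_analysis",
    "run_psa",
    "ceac",
    "ce_plane",
    "subgroup_analysis",
]

logger = logging.getLogger(__name__)

STRATEGIES = ("standard", "low_dose", "high_dose")
DEFAULT_THRESHOLD = 20_000.0
#: CEAC / EVPI threshold grid: GBP 0 to 50 000 per QALY in 1 000 steps
DEFAULT_THRESHOLD_GRID = tuple(float(v) for v in range(0, 50_001, 1_000))


@dataclass(frozen=True)
class DecisionModel:
    """Everything needed to evaluate one strategy's cost and QALYs."""

    fit: WeibullFit
    transition: DailyTransitionParams = field(
        default_factory=DailyTransitionParams
    )
    utilities: StateUtilities = field(default_factory=StateUtilities)
    costs: StateCosts = field(default_factory=StateCosts)
    intervention_costs: Mapping[str, float] = field(
        default_factory=lambda: {"standard": 0.0, "low_dose": 141.0,
                                 "high_dose": 141.0}
    )
    profile: CovariateProfile = field(
        default_factory=lambda: CovariateProfile(
            ulcer_age_days=197.5, ulcer_area_cm2=3.6, infected=0.4
        )
    )
    strategies: tuple[str, ...] = STRATEGIES
    horizon_days: int = 365
    cohort_size: int = 1000

    def healing_rate(self, strategy: str,
                     coeffs: Sequence[float] | None = None) -> float:
        """lambda = exp(beta0 + x @ beta) for this strategy's profile."""
        c = self.fit.coeffs if coeffs is None else coeffs
        return float(np.exp(linear_predictor(c, self.profile.with_arm(strategy))))

    def evaluate_strategy(self, strategy: str):
        """Cohort trace at the point estimates."""
        rate = self.healing_rate(strategy)
        shape = self.fit.shape
        costs = replace(self.costs,
                        intervention_cost=self.intervention_costs[strategy])
        return run_cohort(
            lambda day: daily_healing_prob(shape, rate, day),
            self.transition, self.utilities, costs,
            horizon_days=self.horizon_days, cohort_size=self.cohort_size,
        )

    def with_profile(self, profile: CovariateProfile) -> "DecisionModel":
        return replace(self, profile=profile)


@dataclass
class CEResult:
    """Per-strategy mean costs/QALYs with increments and dominance labels."""

    table: pd.DataFrame          # index strategy; cost, qaly, d_cost, d_qaly,
                                 # label, icer
    reference: str = "standard"

    def __repr__(self) -> str:  # pragma: no cover
        return f"CEResult(reference={self.reference!r})\n{self.table}"


def nmb(delta_qaly: float, delta_cost: float,
        threshold: float = DEFAULT_THRESHOLD) -> float:
    """Incremental net monetary benefit: threshold * dQALY - dCost."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return threshold * delta_qaly - delta_cost


def dominance(costs: Sequence[float], qalys: Sequence[float],
              labels: Sequence[str] | None = None,
              reference: int = 0) -> pd.DataFrame:
    """Apply the dominance decision rule to aligned cost/QALY vectors.

    A strategy is ``dominant`` when it has strictly more QALYs and strictly
    lower cost than *every* comparator, ``dominated`` when some comparator
    has strictly more QALYs and strictly lower cost, else
    ``non-dominated``.  The ICER versus the reference strategy is reported
    only for non-reference strategies where neither dominates the other
    (otherwise no incremental analysis is necessary and the ICER is NaN).
    """
    costs = np.asarray(costs, dtype=float)
    qalys = np.asarray(qalys, dtype=float)
    if costs.shape != qalys.shape:
        raise ValueError("costs and qalys must be aligned")
    n = len(costs)
    labels = list(labels) if labels is not None else [f"s{i}" for i in range(n)]
    out_labels, icers, notes = [], [], []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        if others and all(qalys[i] > qalys[j] and costs[i] < costs[j]
                          for j in others):
            out_labels.append("dominant")
        elif any(qalys[j] > qalys[i] and costs[j] < costs[i] for j in others):
            out_labels.append("dominated")
        else:
            out_labels.append("non-dominated")

        dq = qalys[i] - qalys[reference]
        dc = costs[i] - costs[reference]
        if i == reference:
            icers.append(np.nan)
            notes.append("reference")
        elif (dq > 0 and dc < 0) or (dq < 0 and dc > 0):
            icers.append(np.nan)
            notes.append("no incremental analysis necessary (dominance)")
        elif dq == 0:
            icers.append(np.nan)
            notes.append("ICER undefined (equal QALYs)")
        else:
            icers.append(dc / dq)
            notes.append("")
    return pd.DataFrame(
        {"label": out_labels, "icer_vs_reference": icers, "note": notes},
        index=labels,
    )


def incremental_table(costs: Sequence[float], qalys: Sequence[float],
                      labels: Sequence[str],
                      reference: str | None = None) -> pd.DataFrame:
    """Cost/QALY table with increments vs the reference plus dominance.

    Increments are plain arithmetic differences of the supplied means, so
    this also serves to recompute a published table's difference columns.
    """
    labels = list(labels)
    ref = labels[0] if reference is None else reference
    table = pd.DataFrame({"cost": costs, "qaly": qalys}, index=labels)
    table["d_cost"] = table["cost"] - table.loc[ref, "cost"]
    table["d_qaly"] = table["qaly"] - table.loc[ref, "qaly"]
    dom = dominance(table["cost"], table["qaly"], labels=labels,
                    reference=labels.index(ref))
    return table.join(dom)


def deterministic_analysis(model: DecisionModel,
                           reference: str = "standard") -> CEResult:
    """Base-case costs and QALYs per strategy at the point estimates."""
    if len(model.strategies) < 2:
        raise ValueError("need at least two strategies")
    costs, qalys = [], []
    for s in model.strategies:
        trace = model.evaluate_strategy(s)
        costs.append(trace.cum_cost)
        qalys.append(trace.cum_qaly)
    table = incremental_table(costs, qalys, list(model.strategies),
                              reference=reference)
    return CEResult(table=table, reference=reference)


@dataclass
class PsaResult:
    """Per-draw cost/QALY pairs per strategy plus run metadata."""

    costs: pd.DataFrame            # n_iter x strategies
    qalys: pd.DataFrame
    strategies: tuple[str, ...]
    seed: int
    n_iter: int
    n_redrawn: int = 0
    params: dict[str, np.ndarray] = field(default_factory=dict)
    coeff_draws: np.ndarray | None = None

    def nmb_matrix(self, threshold: float) -> np.ndarray:
        """(n_iter, n_strategies) absolute NMB at one threshold."""
        return (threshold * self.qalys.to_numpy()
                - self.costs.to_numpy())

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean_cost": self.costs.mean(), "mean_qaly": self.qalys.mean()}
        )


@dataclass(frozen=True)
class SubgroupProfile:
    """One cell of the subgroup grid."""

    infected: int
    area_cm2: float
    duration_days: float

    def covariates(self) -> CovariateProfile:
        return CovariateProfile(
            ulcer_age_days=self.duration_days,
            ulcer_area_cm2=self.area_cm2,
            infected=float(self.infected),
        )


#: the published six-scenario subgroup grid
DEFAULT_SUBGROUPS = tuple(
    SubgroupProfile(infected=inf, area_cm2=a, duration_days=d)
    for inf in (1, 0)
    for a, d in ((1.0, 30.0), (5.0, 90.0), (10.0, 180.0))
)


class _PsaSampler:
    """Joint parameter draws for the PSA and value-of-information loops."""

    def __init__(self, model: DecisionModel, dists: ParameterDistributions):
        self.model = model
        self.dists = dists
        self.L = cholesky(model.fit)

    def draw_survival(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return sample_coefficients(self.model.fit, self.L, n, seed=rng)

    def max_exit_excess(self, theta: np.ndarray,
                        other: Mapping[str, np.ndarray]) -> np.ndarray:
        """How far each draw's worst-case open-state exit sum exceeds 1."""
        model = self.model
        if model.fit.family == "weibull":
            shape = np.exp(theta[:, 0])
            coeffs = theta[:, 1:]
        else:
            shape = np.ones(len(theta))
            coeffs = theta
        H = model.horizon_days
        worst = np.zeros(len(theta))
        for s in model.strategies:
            x = model.profile.with_arm(s).design_row()
            rate = np.exp(coeffs @ x)
            # the daily healing probability is monotone in t (direction set
            # by the shape), so its maximum is at day 0 or the last day
            p0 = 1.0 - np.exp(-rate)
            plast = 1.0 - np.exp(-rate * (H ** shape - (H - 1.0) ** shape))
            worst = np.maximum(worst, np.maximum(p0, plast))
        exits = (worst + other["p_open_to_amputee"] + other["p_open_to_dead"])
        return exits - 1.0

    def draw(self, rng: np.random.Generator, n: int,
             max_attempts: int = 100) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """n valid joint draws; invalid ones (exit probs > 1) are redrawn."""
        theta = self.draw_survival(rng, n)
        other = self.dists.sample(rng, n)
        n_redrawn = 0
        for _ in range(max_attempts):
            bad = self.max_exit_excess(theta, other) > 0
            if not np.any(bad):
                break
            k = int(bad.sum())
            n_redrawn += k
            theta[bad] = self.draw_survival(rng, k)
            redraw = self.dists.sample(rng, k)
            for key in other:
                other[key][bad] = redraw[key]
        else:
            raise ValueError(
                "could not draw a valid parameter set after "
                f"{max_attempts} redraw rounds"
            )
        if n_redrawn:
            logger.info("redrew %d invalid PSA draw(s)", n_redrawn)
        other["_n_redrawn"] = np.array([n_redrawn])
        return theta, other

    def evaluate(self, theta: np.ndarray, other: Mapping[str, np.ndarray]
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Run the cohort model for every draw and strategy."""
        model = self.model
        n = len(theta)
        if model.fit.family == "weibull":
            shape = np.exp(theta[:, 0])
            coeffs = theta[:, 1:]
        else:
            shape = np.ones(n)
            coeffs = theta
        utilities = np.column_stack(
            [other["u_open"], other["u_amputee"], other["u_healed"]]
        )
        daily_costs = np.column_stack(
            [other["c_open"], other["c_amputee"], other["c_healed"]]
        )
        costs_out, qalys_out = {}, {}
        for s in model.strategies:
            x = model.profile.with_arm(s).design_row()
            rate = np.exp(coeffs @ x)
            c, q = run_cohort_batch(
                shape, rate,
                other["p_open_to_amputee"], other["p_open_to_dead"],
                other["p_amputee_to_dead"], other["p_healed_to_open"],
                other["p_healed_to_dead"],
                utilities, daily_costs,
                intervention_cost=model.intervention_costs[s],
                amputation_event_cost=model.costs.amputation_event_cost,
                horizon_days=model.horizon_days,
            )
            costs_out[s], qalys_out[s] = c, q
        return pd.DataFrame(costs_out), pd.DataFrame(qalys_out)


def run_psa(model: DecisionModel, dists: ParameterDistributions,
            n_iter: int = 1000, seed: int = 0) -> PsaResult:
    """Probabilistic sensitivity analysis: ``n_iter`` joint-draw model runs.

    Survival coefficients are drawn correlated (Cholesky); transition
    probabilities, costs and utilities independently from ``dists``.  Any
    draw whose open-state exit probabilities could exceed 1 is rejected and
    redrawn (count logged and recorded).  Same seed, same result.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    sampler = _PsaSampler(model, dists)
    rng = np.random.default_rng(seed)
    theta, other = sampler.draw(rng, n_iter)
    n_redrawn = int(other.pop("_n_redrawn")[0])
    costs, qalys = sampler.evaluate(theta, other)
    return PsaResult(
        costs=costs, qalys=qalys, strategies=tuple(model.strategies),
        seed=seed, n_iter=n_iter, n_redrawn=n_redrawn,
        params={k: v for k, v in other.items()}, coeff_draws=theta,
    )


def ceac(psa: PsaResult,
         thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID) -> pd.DataFrame:
    """P(highest NMB) per strategy across thresholds; ties split equally."""
    if psa.n_iter < 1:
        raise ValueError("PSA has no draws")
    rows = []
    for k in thresholds:
        nmb_mat = psa.nmb_matrix(k)
        best = nmb_mat.max(axis=1, keepdims=True)
        is_best = nmb_mat == best
        weights = is_best / is_best.sum(axis=1, keepdims=True)
        probs = weights.mean(axis=0)
        rows.append({"threshold": float(k),
                     **dict(zip(psa.strategies, probs))})
    return pd.DataFrame(rows)


def ce_plane(psa: PsaResult, reference: str = "standard") -> pd.DataFrame:
    """Per-draw incremental cost/QALY pairs versus the reference strategy."""
    frames = []
    for s in psa.strategies:
        if s == reference:
            continue
        frames.append(pd.DataFrame({
            "strategy": s,
            "draw": np.arange(psa.n_iter),
            "d_cost": psa.costs[s] - psa.costs[reference],
            "d_qaly": psa.qalys[s] - psa.qalys[reference],
        }))
    return pd.concat(frames, ignore_index=True)


def subgroup_analysis(model: DecisionModel, dists: ParameterDistributions,
                      profiles: Sequence[SubgroupProfile] = DEFAULT_SUBGROUPS,
                      threshold: float = DEFAULT_THRESHOLD,
                      n_iter: int = 1000, seed: int = 0,
                      reference: str = "standard") -> pd.DataFrame:
    """Incremental NMB of each active strategy vs standard care per profile.

    Each profile re-runs the PSA with the ulcer covariates fixed at the
    profile (same seed for every profile, so profiles differ only through
    the covariates) and computes NMB from the PSA mean costs and QALYs.
    Profiles outside the observed covariate support only warrant a warning,
    not a failure.
    """
    rows = []
    for prof in profiles:
        cov = prof.covariates()
        if not (0.5 <= cov.ulcer_area_cm2 <= 12.0
                and 30.0 <= cov.ulcer_age_days <= 365.0):
            logger.warning(
                "subgroup profile %r outside the default covariate support",
                prof,
            )
        psa = run_psa(model.with_profile(cov), dists,
                      n_iter=n_iter, seed=seed)
        mean_cost = psa.costs.mean()
        mean_qaly = psa.qalys.mean()
        for s in model.strategies:
            if s == reference:
                continue
            rows.append({
                "infected": prof.infected,
                "area_cm2": prof.area_cm2,
                "duration_days": prof.duration_days,
                "strategy": s,
                "inc_nmb": nmb(mean_qaly[s] - mean_qaly[reference],
                               mean_cost[s] - mean_cost[reference],
                               threshold),
            })
    return pd.DataFrame(rows)
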