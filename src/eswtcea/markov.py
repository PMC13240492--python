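"""Four-state, one-day-cycle Markov cohort engine.

States: open DFU (A), amputee (B), healed (C), dead (D); dead is absorbing.
The whole cohort starts with an open ulcer.  Each cycle is one day; the
horizon is one year (365 cycles) with no discounting and no half-cycle
correction — a half-cycle correction buys nothing at a one-day cycle
length.  Daily exit probabilities from the open state are: healing (from
the survival model, time-varying), amputation and death (fixed daily
probabilities); healed ulcers can recur or die; amputees can die.

Costs accrue as per-day state costs plus optional one-off costs (the
intervention at day 0, and optionally an amputation event cost).  QALYs
accrue as annual state utilities divided by 365.  Occupancy, cost and QALY
streams are recorded at the start of each cycle, before that cycle's
transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "HealthState",
    "DailyTransitionParams",
    "StateUtilities",
    "StateCosts",
    "CohortTrace",
    "build_transition_row",
    "run_cohort",
    "run_cohort_batch",
    "trace_summary",
]


class HealthState(IntEnum):
    OPEN = 0
    AMPUTEE = 1
    HEALED = 2
    DEAD = 3


@dataclass(frozen=True)
class DailyTransitionParams:
    """Fixed daily transition probabilities (healing is supplied separately)."""

    p_open_to_amputee: float = 0.00308674
    p_open_to_dead: float = 0.00019921
    p_amputee_to_dead: float = 0.000456958
    p_healed_to_open: float = 0.00308674      # recurrence
    p_healed_to_dead: float = 6.0435e-05

    def validate(self) -> None:
        for name in ("p_open_to_amputee", "p_open_to_dead",
                     "p_amputee_to_dead", "p_healed_to_open",
                     "p_healed_to_dead"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_open_to_amputee + self.p_open_to_dead > 1.0:
            raise ValueError("open-state exits exceed 1 before healing")
        if self.p_healed_to_open + self.p_healed_to_dead > 1.0:
            raise ValueError("healed-state exits exceed 1")


@dataclass(frozen=True)
class StateUtilities:
    """Annual utility weights per state (dead fixed at 0)."""

    u_open: float = 0.671
    u_amputee: float = 0.316
    u_healed: float = 0.757

    def validate(self) -> None:
        for name in ("u_open", "u_amputee", "u_healed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def as_vector(self) -> np.ndarray:
        return np.array([self.u_open, self.u_amputee, self.u_healed, 0.0])


@dataclass(frozen=True)
class StateCosts:
    """Per-day state costs (GBP) plus one-off costs.

    ``intervention_cost`` is charged once at day 0 (e.g. the ESWT course);
    ``amputation_event_cost`` is charged per transition into the amputee
    state (default 0: the base analysis carries amputation cost entirely in
    the daily amputee-state cost).
    """

    c_open: float = 15.01
    c_amputee: float = 22.64
    c_healed: float = 1.89
    intervention_cost: float = 0.0
    amputation_event_cost: float = 0.0

    def validate(self) -> None:
        for name in ("c_open", "c_amputee", "c_healed",
                     "intervention_cost", "amputation_event_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def as_vector(self) -> np.ndarray:
        return np.array([self.c_open, self.c_amputee, self.c_healed, 0.0])


@dataclass
class CohortTrace:
    """Per-cycle occupancy plus accumulated per-patient cost and QALYs."""

    occupancy: np.ndarray          # (horizon+1, 4); row h = start of cycle h
    cycle_cost: np.ndarray         # (horizon,) per patient
    cycle_qaly: np.ndarray         # (horizon,) per patient
    new_amputees: np.ndarray       # (horizon,) inflow into AMPUTEE per cycle
    cohort_size: int = 1000

    @property
    def horizon_days(self) -> int:
        return len(self.cycle_cost)

    @property
    def cum_cost(self) -> float:
        """Total cost per patient over the horizon."""
        return float(self.cycle_cost.sum())

    @property
    def cum_qaly(self) -> float:
        """Total QALYs per patient over the horizon."""
        return float(self.cycle_qaly.sum())

    @property
    def cohort_cost(self) -> float:
        return self.cum_cost * self.cohort_size

    @property
    def cohort_qaly(self) -> float:
        return self.cum_qaly * self.cohort_size

    def to_frame(self) -> pd.DataFrame:
        """cycle, state occupancies, per-cycle cost and QALY streams."""
        h = self.horizon_days
        return pd.DataFrame(
            {
                "cycle": np.arange(h),
                "p_open": self.occupancy[:h, HealthState.OPEN],
                "p_amputee": self.occupancy[:h, HealthState.AMPUTEE],
                "p_healed": self.occupancy[:h, HealthState.HEALED],
                "p_dead": self.occupancy[:h, HealthState.DEAD],
                "cycle_cost": self.cycle_cost,
                "cycle_qaly": self.cycle_qaly,
            }
        )


def build_transition_row(state: HealthState, day: int,
                         params: DailyTransitionParams,
                         healing_prob_fn: Callable[[int], float]) -> np.ndarray:
    """One row of the day-``day`` transition matrix; sums to 1 exactly."""
    if day < 0:
        raise ValueError("day must be >= 0")
    row = np.zeros(4)
    if state == HealthState.OPEN:
        p_heal = float(healing_prob_fn(day))
        exits = p_heal + params.p_open_to_amputee + params.p_open_to_dead
        if not 0.0 <= p_heal <= 1.0 or exits > 1.0:
            raise ValueError(
                f"exit probabilities from OPEN exceed 1 at day {day} "
                f"(healing={p_heal:.6g})"
            )
        row[HealthState.HEALED] = p_heal
        row[HealthState.AMPUTEE] = params.p_open_to_amputee
        row[HealthState.DEAD] = params.p_open_to_dead
        row[HealthState.OPEN] = 1.0 - exits
    elif state == HealthState.AMPUTEE:
        row[HealthState.DEAD] = params.p_amputee_to_dead
        row[HealthState.AMPUTEE] = 1.0 - params.p_amputee_to_dead
    elif state == HealthState.HEALED:
        exits = params.p_healed_to_open + params.p_healed_to_dead
        if exits > 1.0:
            raise ValueError(
                f"exit probabilities from HEALED exceed 1 at day {day}"
            )
        row[HealthState.OPEN] = params.p_healed_to_open
        row[HealthState.DEAD] = params.p_healed_to_dead
        row[HealthState.HEALED] = 1.0 - exits
    elif state == HealthState.DEAD:
        row[HealthState.DEAD] = 1.0
    else:  # pragma: no cover
        raise ValueError(f"unknown state {state!r}")
    return row


def run_cohort(healing_prob_fn: Callable[[int], float],
               params: DailyTransitionParams,
               utilities: StateUtilities,
               costs: StateCosts,
               horizon_days: int = 365,
               cohort_size: int = 1000,
               initial: np.ndarray | None = None) -> CohortTrace:
    """Run the cohort for ``horizon_days`` one-day cycles.

    ``healing_prob_fn(day)`` gives the probability of healing during cycle
    ``day`` for the open state (day 0 is the first cycle, i.e. model entry).
    Costs and QALYs for cycle ``day`` accrue on the occupancy at the start
    of that cycle; the intervention one-off is added at cycle 0.
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    params.validate()
    utilities.validate()
    costs.validate()

    occ = np.zeros((horizon_days + 1, 4))
    occ[0] = (np.array([1.0, 0.0, 0.0, 0.0]) if initial is None
              else np.asarray(initial, dtype=float))
    if abs(occ[0].sum() - 1.0) > 1e-10 or np.any(occ[0] < 0):
        raise ValueError("initial distribution must be a probability vector")

    u = utilities.as_vector()
    c = costs.as_vector()
    cycle_cost = np.zeros(horizon_days)
    cycle_qaly = np.zeros(horizon_days)
    new_amputees = np.zeros(horizon_days)

    for day in range(horizon_days):
        cur = occ[day]
        cycle_qaly[day] = float(cur @ u) / 365.0
        cycle_cost[day] = float(cur @ c)
        if day == 0:
            cycle_cost[day] += costs.intervention_cost
        P = np.vstack(
            [build_transition_row(HealthState(s), day, params, healing_prob_fn)
             for s in range(4)]
        )
        nxt = cur @ P
        inflow_amp = cur[HealthState.OPEN] * params.p_open_to_amputee
        new_amputees[day] = inflow_amp
        cycle_cost[day] += inflow_amp * costs.amputation_event_cost
        occ[day + 1] = nxt

    return CohortTrace(
        occupancy=occ,
        cycle_cost=cycle_cost,
        cycle_qaly=cycle_qaly,
        new_amputees=new_amputees,
        cohort_size=cohort_size,
    )


def run_cohort_batch(shape: np.ndarray, rate: np.ndarray,
                     p_open_to_amputee: np.ndarray,
                     p_open_to_dead: np.ndarray,
                     p_amputee_to_dead: np.ndarray,
                     p_healed_to_open: np.ndarray,
                     p_healed_to_dead: np.ndarray,
                     utilities: np.ndarray,
                     daily_costs: np.ndarray,
                     intervention_cost: np.ndarray | float = 0.0,
                     amputation_event_cost: np.ndarray | float = 0.0,
                     horizon_days: int = 365,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised cohort runs for many parameter draws at once.

    All per-draw inputs are length-``n`` arrays (``utilities`` and
    ``daily_costs`` are ``(n, 3)`` for open/amputee/healed); the healing
    probability at cycle t is ``1 - exp(-rate * ((t+1)**shape - t**shape))``.
    Returns per-patient ``(cost, qaly)`` arrays of length ``n``.  This is
    the engine behind the probabilistic and value-of-information analyses;
    draw-by-draw it matches :func:`run_cohort` exactly.
    """
    shape = np.atleast_1d(np.asarray(shape, dtype=float))
    rate = np.atleast_1d(np.asarray(rate, dtype=float))
    n = len(shape)
    u = np.column_stack([np.asarray(utilities, dtype=float),
                         np.zeros(n)])
    c = np.column_stack([np.asarray(daily_costs, dtype=float),
                         np.zeros(n)])
    occ = np.zeros((n, 4))
    occ[:, HealthState.OPEN] = 1.0

    cost = np.zeros(n) + np.asarray(intervention_cost, dtype=float)
    qaly = np.zeros(n)
    amp_cost = np.asarray(amputation_event_cost, dtype=float)

    t_pow = np.zeros(n)                       # t**shape at t = 0
    for day in range(horizon_days):
        qaly += np.einsum("ij,ij->i", occ, u) / 365.0
        cost += np.einsum("ij,ij->i", occ, c)

        t1_pow = (day + 1.0) ** shape
        p_heal = 1.0 - np.exp(-rate * (t1_pow - t_pow))
        t_pow = t1_pow

        exits_open = p_heal + p_open_to_amputee + p_open_to_dead
        if np.any(exits_open > 1.0 + 1e-12):
            bad = int(np.sum(exits_open > 1.0 + 1e-12))
            raise ValueError(
                f"exit probabilities from OPEN exceed 1 at day {day} "
                f"for {bad} draw(s)"
            )

        o, a, h, dd = (occ[:, 0].copy(), occ[:, 1].copy(),
                       occ[:, 2].copy(), occ[:, 3].copy())
        inflow_amp = o * p_open_to_amputee
        cost += inflow_amp * amp_cost
        occ[:, 0] = o * (1.0 - exits_open) + h * p_healed_to_open
        occ[:, 1] = a * (1.0 - p_amputee_to_dead) + inflow_amp
        occ[:, 2] = (h * (1.0 - p_healed_to_open - p_healed_to_dead)
                     + o * p_heal)
        occ[:, 3] = (dd + o * p_open_to_dead + a * p_amputee_to_dead
                     + h * p_healed_to_dead)
    return cost, qaly


def trace_summary(trace: CohortTrace) -> pd.DataFrame:
    """Per-state expected days in state, plus cumulative deaths/amputations.

    Time in state sums over the accrual rows, so the per-state days add up
    to the horizon exactly.
    """
    h = trace.horizon_days
    days = trace.occupancy[:h].sum(axis=0)
    return pd.DataFrame(
        {
            "days_open": [days[HealthState.OPEN]],
            "days_amputee": [days[HealthState.AMPUTEE]],
            "days_healed": [days[HealthState.HEALED]],
            "days_dead": [days[HealthState.DEAD]],
            "cum_deaths": [trace.occupancy[h, HealthState.DEAD]],
            "cum_amputations": [float(trace.new_amputees.sum())],
        }
    )
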