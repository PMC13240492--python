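"""Value-of-information analysis: EVPI, population EVPI and EVPPI.

EVPI (expected value of perfect information) is the mean opportunity loss
of deciding under current information: per PSA draw, the loss is the best
achievable net monetary benefit (NMB) minus the NMB of the strategy that is
best on average; averaging over draws gives the per-patient EVPI.
Population EVPI scales the per-patient value by the number of patients the
decision affects (annual incidence times the decision horizon, undiscounted
over a one-year horizon).

EVPPI (expected value of *partial* perfect information) for a parameter
group is estimated by nested two-level Monte Carlo: the outer loop fixes
the group at a fresh draw, the inner loop integrates the remaining
parameters (survival coefficients conditionally, preserving their
correlation), and

    EVPPI = E_outer[ max_s E_inner[NMB_s] ] - max_s E[NMB_s].

Monte-Carlo noise can make the estimate slightly negative; it is floored at
0 and the raw value kept alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import (DEFAULT_THRESHOLD, DEFAULT_THRESHOLD_GRID, DecisionModel,
                  PsaResult, _PsaSampler)
from .distributions import ParameterDistributions

__all__ = [
    "PARAMETER_GROUPS",
    "VoiResult",
    "evpi_per_patient",
    "population_evpi",
    "evpi_curve",
    "evppi",
    "nested_evppi",
    "voi_analysis",
]

logger = logging.getLogger(__name__)

#: registered EVPPI parameter groups.  ``high_dose_effect`` is the
#: high-dose coefficient of the survival model only; the cost and utility
#: groups are the three daily state costs / three state utilities.
PARAMETER_GROUPS: dict[str, dict] = {
    "high_dose_effect": {"survival": ("high_dose",), "other": ()},
    "state_costs": {"survival": (), "other": ("c_open", "c_amputee",
                                              "c_healed")},
    "state_utilities": {"survival": (), "other": ("u_open", "u_amputee",
                                                  "u_healed")},
    "all": {"survival": "all", "other": "all"},
}

_OTHER_FIELDS = ParameterDistributions._FIELDS


@dataclass
class VoiResult:
    evpi_per_patient: float
    population_evpi: dict[float, float]
    evppi_per_patient: dict[str, float]
    evppi_raw: dict[str, float]
    threshold: float
    inner: int
    outer: int

    def summary(self) -> pd.DataFrame:
        rows = [{"quantity": "evpi_per_patient",
                 "value": self.evpi_per_patient}]
        for inc, v in self.population_evpi.items():
            rows.append({"quantity": f"population_evpi_{int(inc)}",
                         "value": v})
        for g, v in self.evppi_per_patient.items():
            rows.append({"quantity": f"evppi_{g}", "value": v})
        return pd.DataFrame(rows)


def evpi_per_patient(psa: PsaResult,
                     threshold: float = DEFAULT_THRESHOLD) -> float:
    """Mean of per-draw best NMB minus best mean NMB (always >= 0)."""
    if psa.n_iter < 2 or len(psa.strategies) < 2:
        raise ValueError("EVPI needs >= 2 draws and >= 2 strategies")
    nmb = psa.nmb_matrix(threshold)
    return float(nmb.max(axis=1).mean() - nmb.mean(axis=0).max())


def population_evpi(evpi_pp: float, incidence_per_year: float,
                    horizon_years: float = 1.0,
                    discount_rate: float = 0.0) -> float:
    """Per-patient EVPI scaled to the affected population.

    With a one-year decision horizon and no discounting this is simply
    ``evpi_pp * incidence * horizon``; a positive discount rate applies a
    standard annuity weighting over whole years.
    """
    if incidence_per_year < 0:
        raise ValueError("incidence must be >= 0")
    if discount_rate == 0.0:
        effective = incidence_per_year * horizon_years
    else:
        years = int(round(horizon_years))
        effective = incidence_per_year * sum(
            (1.0 + discount_rate) ** -y for y in range(years)
        )
    return evpi_pp * effective


def evpi_curve(psa: PsaResult,
               thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
               incidences: Sequence[float] = (50_000.0, 100_000.0),
               ) -> pd.DataFrame:
    """EVPI and the probability the preferred strategy is cost-effective,
    per willingness-to-pay threshold."""
    if len(thresholds) == 0:
        raise ValueError("threshold grid is empty")
    rows = []
    for k in thresholds:
        nmb = psa.nmb_matrix(k)
        means = nmb.mean(axis=0)
        preferred = int(np.argmax(means))
        evpi = float(nmb.max(axis=1).mean() - means[preferred])
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb == best
        p_ce = float((is_best / is_best.sum(axis=1, keepdims=True))
                     [:, preferred].mean())
        row = {
            "threshold": float(k),
            "evpi_per_patient": evpi,
            "preferred_strategy": psa.strategies[preferred],
            "p_preferred_cost_effective": p_ce,
        }
        for inc in incidences:
            row[f"population_evpi_{int(inc)}"] = population_evpi(evpi, inc)
        rows.append(row)
    return pd.DataFrame(rows)


def _evppi_reduce(nmb: np.ndarray, outer: int, inner: int) -> float:
    """E_outer[max_s E_inner[NMB]] - max_s E[NMB] from a stacked NMB matrix
    (outer*inner rows ordered outer-major, one column per strategy)."""
    n_strat = nmb.shape[1]
    inner_means = nmb.reshape(outer, inner, n_strat).mean(axis=1)
    return float(inner_means.max(axis=1).mean() - nmb.mean(axis=0).max())


def nested_evppi(draw_group, draw_rest_given, nmb_fn, outer: int, inner: int,
                 rng: np.random.Generator) -> tuple[float, float]:
    """Generic two-level nested EVPPI estimator.

    ``draw_group(rng, n)`` draws n outer values of the group (n, dg);
    ``draw_rest_given(rng, group_rows)`` completes each row to a full
    parameter matrix; ``nmb_fn(params)`` maps parameter rows to an
    ``(n, n_strategies)`` NMB matrix.  Returns ``(evppi, raw)`` with the
    estimate floored at 0.
    """
    if outer < 2 or inner < 1:
        raise ValueError("need outer >= 2 and inner >= 1")
    g = np.asarray(draw_group(rng, outer))
    g_rows = np.repeat(g, inner, axis=0)
    params = draw_rest_given(rng, g_rows)
    nmb = np.asarray(nmb_fn(params), dtype=float)
    raw = _evppi_reduce(nmb, outer, inner)
    return max(raw, 0.0), raw


def _conditional_survival_draw(fit, L, group_idx: np.ndarray,
                               theta_group: np.ndarray,
                               rng: np.random.Generator) -> np.ndarray:
    """Draw the remaining survival parameters given the group's values.

    Standard Gaussian conditioning on the fit's covariance, so the
    correlation between the fixed coefficient(s) and the rest is preserved.
    Returns the full parameter matrix with the group columns set to
    ``theta_group``.
    """
    mu = fit.params
    Sigma = 0.5 * (fit.vcov + fit.vcov.T)
    k = len(mu)
    rest_idx = np.array([i for i in range(k) if i not in set(group_idx)])
    S_gg = Sigma[np.ix_(group_idx, group_idx)]
    S_rg = Sigma[np.ix_(rest_idx, group_idx)]
    S_rr = Sigma[np.ix_(rest_idx, rest_idx)]
    solve = np.linalg.solve(S_gg, (theta_group - mu[group_idx]).T).T
    cond_mean = mu[rest_idx] + solve @ S_rg.T
    cond_cov = S_rr - S_rg @ np.linalg.solve(S_gg, S_rg.T)
    cond_cov = 0.5 * (cond_cov + cond_cov.T)
    w, V = np.linalg.eigh(cond_cov)
    Lc = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((len(theta_group), len(rest_idx)))
    theta = np.empty((len(theta_group), k))
    theta[:, group_idx] = theta_group
    theta[:, rest_idx] = cond_mean + z @ Lc.T
    return theta


def evppi(model: DecisionModel, dists: ParameterDistributions,
          group: str, threshold: float = DEFAULT_THRESHOLD,
          outer: int = 250, inner: int = 1000, seed: int = 0,
          chunk_size: int = 50_000) -> tuple[float, float]:
    """Nested-simulation EVPPI for a registered parameter group.

    Returns ``(evppi, raw)`` where ``evppi = max(raw, 0)``; a small
    negative ``raw`` is Monte-Carlo noise.  The empty group has EVPPI 0 by
    definition and is returned exactly.
    """
    if group == "":
        return 0.0, 0.0
    if group not in PARAMETER_GROUPS:
        raise KeyError(
            f"unknown parameter group {group!r}; registered groups: "
            f"{sorted(PARAMETER_GROUPS)}"
        )
    if outer < 2 or inner < 1:
        raise ValueError("need outer >= 2 and inner >= 1")
    spec = PARAMETER_GROUPS[group]
    sampler = _PsaSampler(model, dists)
    fit = model.fit
    rng = np.random.default_rng(seed)

    all_survival = spec["survival"] == "all"
    all_other = spec["other"] == "all"
    if all_survival and all_other:
        inner = 1  # perfect information on everything: inner loop is trivial

    names = fit.param_names
    surv_group_idx = (np.arange(len(names)) if all_survival else
                      np.array([names.index(n) for n in spec["survival"]],
                               dtype=int))
    other_group = (set(_OTHER_FIELDS) if all_other else set(spec["other"]))

    n_total = outer * inner

    # outer draws of the group, repeated across the inner loop
    theta_outer = sampler.draw_survival(rng, outer)
    other_outer = dists.sample(rng, outer)

    def build(bad: np.ndarray | None = None) -> tuple[np.ndarray, dict]:
        """(Re)build joint draws; if ``bad`` is given, redraw only the
        complement for those rows, keeping the group values fixed."""
        m = n_total if bad is None else int(bad.sum())
        rows = np.arange(n_total) if bad is None else np.flatnonzero(bad)
        out_idx = rows // inner
        if len(surv_group_idx) == len(names):
            theta = np.repeat(theta_outer, inner, axis=0)[rows]
        elif len(surv_group_idx) == 0:
            theta = sampler.draw_survival(rng, m)
        else:
            theta_g = theta_outer[:, surv_group_idx][out_idx]
            theta = _conditional_survival_draw(fit, sampler.L,
                                               surv_group_idx, theta_g, rng)
        inner_other = dists.sample(rng, m)
        other = {}
        for f in _OTHER_FIELDS:
            if f in other_group:
                other[f] = other_outer[f][out_idx]
            else:
                other[f] = inner_other[f]
        return theta, other

    theta, other = build()
    for _ in range(100):
        bad = sampler.max_exit_excess(theta, other) > 0
        if not np.any(bad):
            break
        logger.info("redrawing %d invalid nested draw(s)", int(bad.sum()))
        theta_new, other_new = build(bad)
        theta[bad] = theta_new
        for f in _OTHER_FIELDS:
            other[f][bad] = other_new[f]
    else:
        raise ValueError("could not produce valid nested draws")

    n_strat = len(model.strategies)
    nmb = np.empty((n_total, n_strat))
    for start in range(0, n_total, chunk_size):
        sl = slice(start, min(start + chunk_size, n_total))
        costs, qalys = sampler.evaluate(
            theta[sl], {f: other[f][sl] for f in _OTHER_FIELDS}
        )
        nmb[sl] = threshold * qalys.to_numpy() - costs.to_numpy()

    raw = _evppi_reduce(nmb, outer, inner)
    if raw < 0:
        logger.info("EVPPI(%s) raw estimate %.4g < 0; flooring at 0",
                    group, raw)
    return max(raw, 0.0), raw


def voi_analysis(model: DecisionModel, dists: ParameterDistributions,
                 psa: PsaResult, threshold: float = DEFAULT_THRESHOLD,
                 incidences: Sequence[float] = (50_000.0, 100_000.0),
                 groups: Sequence[str] = ("high_dose_effect", "state_costs",
                                          "state_utilities"),
                 inner: int = 1000, outer: int = 250,
                 seed: int = 0) -> VoiResult:
    """EVPI (from an existing PSA) plus nested EVPPI for each group."""
    evpi_pp = evpi_per_patient(psa, threshold)
    pop = {float(inc): population_evpi(evpi_pp, inc) for inc in incidences}
    evppi_pp, raw = {}, {}
    for g in groups:
        evppi_pp[g], raw[g] = evppi(model, dists, g, threshold=threshold,
                                    outer=outer, inner=inner, seed=seed)
    return VoiResult(
        evpi_per_patient=evpi_pp, population_evpi=pop,
        evppi_per_patient=evppi_pp, evppi_raw=raw,
        threshold=threshold, inner=inner, outer=outer,
    )
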