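"""Synthetic three-arm pilot-trial generator.

The downstream analysis assumes an individual-level dataset from a small
randomised trial of extracorporeal shockwave therapy (ESWT) for diabetic
foot ulcers (DFUs): 74 patients, three arms (standard care / low-dose /
high-dose ESWT), six months of follow-up, with time-to-healing right-censored
at the end of follow-up.  No such dataset is public, so this module generates
one with exactly the statistical structure the analysis fits:

* healing times follow a Weibull proportional-hazards model,
  ``h(t|x) = gamma * lambda * t**(gamma-1)`` with
  ``lambda = exp(beta0 + x @ beta)``, where the covariates are the two
  treatment indicators, ulcer age (days), ulcer area (cm^2) and infection
  status;
* amputation and death compete as independent daily Bernoulli events,
  mirroring the memoryless competing structure of the cohort model;
* per-state EQ-5D-style utility observations and resource-use counts are
  drawn with realistic sampling noise so the utility/costing steps have
  something to estimate.

Times are simulated in continuous time and recorded to the nearest day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARM_LABELS",
    "EVENT_LABELS",
    "RESOURCE_CATEGORIES",
    "TrialConfig",
    "PatientRecord",
    "TrialDataset",
    "generate_trial",
    "price_resource_use",
    "write_trial",
    "read_trial",
]

ARM_LABELS = ("standard", "low_dose", "high_dose")
EVENT_LABELS = ("healed", "amputated", "died", "censored")
STATE_LABELS = ("open", "amputee", "healed")

#: resource-use categories collected per patient, with default unit prices
#: (GBP, outpatient-tariff scale).  These feed the costing of individual
#: resource use; the cohort model's per-state daily costs are configured
#: separately.
RESOURCE_CATEGORIES = (
    "podiatry",
    "mdt",
    "gp",
    "district_nurse",
    "practice_nurse",
    "hospitalisation",
    "dressings",
)

_DEFAULT_UNIT_PRICES = {
    "podiatry": 47.0,
    "mdt": 173.0,
    "gp": 41.0,
    "district_nurse": 44.0,
    "practice_nurse": 15.0,
    "hospitalisation": 2023.0,
    "dressings": 5.0,
}

# mean events per day while occupying each state
_DEFAULT_RESOURCE_RATES = {
    "podiatry": {"open": 0.14, "amputee": 0.03, "healed": 0.01},
    "mdt": {"open": 0.05, "amputee": 0.02, "healed": 0.0},
    "gp": {"open": 0.02, "amputee": 0.02, "healed": 0.01},
    "district_nurse": {"open": 0.10, "amputee": 0.05, "healed": 0.0},
    "practice_nurse": {"open": 0.08, "amputee": 0.02, "healed": 0.01},
    "hospitalisation": {"open": 0.002, "amputee": 0.002, "healed": 0.0},
    "dressings": {"open": 0.40, "amputee": 0.05, "healed": 0.0},
}


def _default_log_hazard_ratios() -> dict[str, float]:
    # Treatment effects: point hazard ratios of 2.0 (high dose) and 1.35
    # (low dose) versus standard care; older, larger and infected ulcers
    # heal more slowly.
    return {
        "low_dose": math.log(1.35),
        "high_dose": math.log(2.0),
        "ulcer_age_days": -0.001,
        "ulcer_area_cm2": -0.04,
        "infected": -0.3,
    }


def _default_covariate_distributions() -> dict[str, object]:
    return {
        "ulcer_age_days": (30.0, 365.0),     # uniform
        "ulcer_area_cm2": (0.5, 12.0),       # log-uniform
        "infected": 0.4,                     # Bernoulli probability
    }


def _default_utility_means_sds() -> dict[str, tuple[float, float]]:
    return {
        "open": (0.671, 0.20),
        "amputee": (0.316, 0.20),
        "healed": (0.757, 0.15),
    }


def _default_daily_event_probs() -> dict[str, float]:
    return {"amputation": 0.00308674, "death": 0.00019921}


def _default_resource_profiles() -> dict[str, dict[str, object]]:
    return {
        cat: {
            "daily_rate": dict(_DEFAULT_RESOURCE_RATES[cat]),
            "unit_price": _DEFAULT_UNIT_PRICES[cat],
        }
        for cat in RESOURCE_CATEGORIES
    }


@dataclass(frozen=True)
class TrialConfig:
    """Full parameterisation of the synthetic trial.

    Defaults emulate the pilot study the analysis is built around: 74
    patients randomised 1:1:1 to sham/low-dose/high-dose ESWT and followed
    for six months (183 days).
    """

    n_patients: int = 74
    arm_labels: tuple[str, ...] = ARM_LABELS
    allocation_ratio: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    followup_days: int = 183
    weibull_shape: float = 1.1
    baseline_log_scale: float = -5.7
    log_hazard_ratios: Mapping[str, float] = field(
        default_factory=_default_log_hazard_ratios
    )
    covariate_distributions: Mapping[str, object] = field(
        default_factory=_default_covariate_distributions
    )
    utility_means_sds: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_utility_means_sds
    )
    daily_event_probs: Mapping[str, float] = field(
        default_factory=_default_daily_event_probs
    )
    resource_profiles: Mapping[str, Mapping[str, object]] = field(
        default_factory=_default_resource_profiles
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError(f"n_patients must be >= 0, got {self.n_patients}")
        if self.followup_days < 1:
            raise ValueError(
                f"followup_days must be >= 1, got {self.followup_days}"
            )
        if not self.weibull_shape > 0:
            raise ValueError(
                f"weibull_shape must be positive, got {self.weibull_shape}"
            )
        if len(self.allocation_ratio) != len(self.arm_labels):
            raise ValueError(
                "allocation_ratio must have one entry per arm label"
            )
        total = float(sum(self.allocation_ratio))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"allocation_ratio must sum to 1 (got {total!r})"
            )
        for key, p in self.daily_event_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"daily_event_probs[{key!r}] not in [0, 1]")
        for state, (m, s) in self.utility_means_sds.items():
            if not 0.0 < m < 1.0:
                raise ValueError(f"utility mean for {state!r} not in (0, 1)")
            if s > 0 and s * s >= m * (1 - m):
                raise ValueError(
                    f"utility sd for {state!r} too large for a beta on (0, 1)"
                )


@dataclass(frozen=True)
class PatientRecord:
    id: int
    arm: str
    ulcer_age_days: float
    ulcer_area_cm2: float
    infected: int
    time_days: float
    event: str
    utility_obs: Mapping[str, float]          # per visited state
    resource_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.event not in EVENT_LABELS:
            raise ValueError(f"unknown event label {self.event!r}")


@dataclass
class TrialDataset:
    records: list[PatientRecord]
    config_echo: TrialConfig | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        # equality is field-for-field on the records; the config echo is
        # provenance and is not serialised to the tabular file
        if not isinstance(other, TrialDataset):
            return NotImplemented
        return self.records == other.records

    def arm_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.arm] = out.get(r.arm, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tabular view, one row per patient (columns as in the CSV)."""
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "id": r.id,
                "arm": r.arm,
                "ulcer_age_days": r.ulcer_age_days,
                "ulcer_area_cm2": r.ulcer_area_cm2,
                "infected": r.infected,
                "time_days": r.time_days,
                "event": r.event,
            }
            for state in STATE_LABELS:
                row[f"u_{state}"] = r.utility_obs.get(state, np.nan)
            for cat in RESOURCE_CATEGORIES:
                row[cat] = r.resource_counts.get(cat, 0)
            rows.append(row)
        cols = (
            ["id", "arm", "ulcer_age_days", "ulcer_area_cm2", "infected",
             "time_days", "event"]
            + [f"u_{s}" for s in STATE_LABELS]
            + list(RESOURCE_CATEGORIES)
        )
        return pd.DataFrame(rows, columns=cols)


def _allocate_arms(n: int, labels: Sequence[str], ratio: Sequence[float],
                   rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation, then a random permutation of slots."""
    raw = np.asarray(ratio, dtype=float) * n
    counts = np.floor(raw).astype(int)
    remainder = int(n - counts.sum())
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    slots = np.repeat(np.arange(len(labels)), counts)
    return np.asarray(labels, dtype=object)[rng.permutation(slots)]


def _beta_moment_match(mean: float, sd: float) -> tuple[float, float]:
    nu = mean * (1 - mean) / (sd * sd) - 1.0
    return mean * nu, (1 - mean) * nu


def _draw_geometric_day(p: float, rng: np.random.Generator) -> float:
    """Day of first success of a daily Bernoulli(p); inf when p == 0."""
    if p <= 0.0:
        return math.inf
    return float(rng.geometric(p))


def generate_trial(config: TrialConfig) -> TrialDataset:
    """Generate an individual-level trial dataset from ``config``.

    Healing times are drawn by inverting the Weibull survival function
    ``S(t) = exp(-lambda * t**gamma)``; amputation and death are daily
    Bernoulli competing events; the first event wins and everything after
    ``followup_days`` is right-censored.  Identical seeds give identical
    datasets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return TrialDataset(records=[], config_echo=config)

    arms = _allocate_arms(n, config.arm_labels, config.allocation_ratio, rng)

    lo_age, hi_age = config.covariate_distributions["ulcer_age_days"]
    lo_area, hi_area = config.covariate_distributions["ulcer_area_cm2"]
    p_inf = float(config.covariate_distributions["infected"])
    ulcer_age = rng.uniform(lo_age, hi_age, size=n)
    ulcer_area = np.exp(
        rng.uniform(math.log(lo_area), math.log(hi_area), size=n)
    )
    infected = (rng.random(n) < p_inf).astype(int)

    hr = config.log_hazard_ratios
    gamma = config.weibull_shape
    eta = (
        config.baseline_log_scale
        + hr.get("ulcer_age_days", 0.0) * ulcer_age
        + hr.get("ulcer_area_cm2", 0.0) * ulcer_area
        + hr.get("infected", 0.0) * infected
        + np.where(arms == "low_dose", hr.get("low_dose", 0.0), 0.0)
        + np.where(arms == "high_dose", hr.get("high_dose", 0.0), 0.0)
    )
    lam = np.exp(eta)

    # inverse-CDF draw: t = (E / lambda)^(1/gamma), E ~ Exp(1)
    t_heal = (rng.exponential(1.0, size=n) / lam) ** (1.0 / gamma)

    p_amp = float(config.daily_event_probs.get("amputation", 0.0))
    p_die = float(config.daily_event_probs.get("death", 0.0))

    beta_params = {
        state: _beta_moment_match(m, s) if s > 0 else None
        for state, (m, s) in config.utility_means_sds.items()
    }

    records: list[PatientRecord] = []
    for i in range(n):
        heal_day = max(1.0, float(round(t_heal[i])))
        amp_day = _draw_geometric_day(p_amp, rng)
        die_day = _draw_geometric_day(p_die, rng)

        # first event wins; healing takes precedence on a tied day
        event, day = "censored", float(config.followup_days)
        for label, d in (("healed", heal_day), ("amputated", amp_day),
                         ("died", die_day)):
            if d <= config.followup_days and d < day or (
                d <= config.followup_days and d == day and event == "censored"
            ):
                event, day = label, d

        visited = ["open"]
        if event == "healed":
            visited.append("healed")
        elif event == "amputated":
            visited.append("amputee")

        utility_obs = {}
        for state in visited:
            params = beta_params[state]
            m, s = config.utility_means_sds[state]
            if params is None:
                utility_obs[state] = m
            else:
                utility_obs[state] = float(rng.beta(*params))

        days_in = {"open": min(day, float(config.followup_days)),
                   "amputee": 0.0, "healed": 0.0}
        if event == "healed":
            days_in["healed"] = config.followup_days - day
        elif event == "amputated":
            days_in["amputee"] = config.followup_days - day

        resource_counts = {}
        for cat, profile in config.resource_profiles.items():
            mean = sum(
                profile["daily_rate"].get(state, 0.0) * days_in[state]
                for state in STATE_LABELS
            )
            resource_counts[cat] = int(rng.poisson(mean))

        records.append(
            PatientRecord(
                id=i,
                arm=str(arms[i]),
                ulcer_age_days=float(ulcer_age[i]),
                ulcer_area_cm2=float(ulcer_area[i]),
                infected=int(infected[i]),
                time_days=day,
                event=event,
                utility_obs=utility_obs,
                resource_counts=resource_counts,
            )
        )
    return TrialDataset(records=records, config_echo=config)


def price_resource_use(counts: Mapping[str, float],
                       unit_prices: Mapping[str, float]) -> float:
    """Total cost of a bundle of resource counts at the given unit prices."""
    missing = sorted(set(counts) - set(unit_prices))
    if missing:
        raise KeyError(
            f"no unit price for resource categories: {', '.join(missing)}"
        )
    for key, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count for {key!r}")
        if unit_prices[key] < 0:
            raise ValueError(f"negative unit price for {key!r}")
    return float(sum(c * unit_prices[k] for k, c in counts.items()))


def write_trial(dataset: TrialDataset, path: str | Path) -> None:
    """Write the dataset as UTF-8 CSV with one header row."""
    dataset.to_frame().to_csv(path, index=False, encoding="utf-8")


def read_trial(path: str | Path) -> TrialDataset:
    """Read a trial CSV written by :func:`write_trial`.

    Malformed rows are rejected with their (1-based, data-row) number.
    """
    frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    expected = (
        ["id", "arm", "ulcer_age_days", "ulcer_area_cm2", "infected",
         "time_days", "event"]
        + [f"u_{s}" for s in STATE_LABELS]
        + list(RESOURCE_CATEGORIES)
    )
    if list(frame.columns) != expected:
        raise ValueError(
            f"unexpected columns {list(frame.columns)!r}; expected {expected!r}"
        )
    records: list[PatientRecord] = []
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            utility_obs = {
                state: float(row[f"u_{state}"])
                for state in STATE_LABELS
                if not pd.isna(row[f"u_{state}"])
            }
            records.append(
                PatientRecord(
                    id=int(row["id"]),
                    arm=str(row["arm"]),
                    ulcer_age_days=float(row["ulcer_age_days"]),
                    ulcer_area_cm2=float(row["ulcer_area_cm2"]),
                    infected=int(row["infected"]),
                    time_days=float(row["time_days"]),
                    event=str(row["event"]),
                    utility_obs=utility_obs,
                    resource_counts={
                        cat: int(row[cat]) for cat in RESOURCE_CATEGORIES
                    },
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed trial record at data row {pos}: {exc}")
    return TrialDataset(records=records, config_echo=None)
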