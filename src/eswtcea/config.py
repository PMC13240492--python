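"""Run configuration: a YAML key-value file over validated dataclasses.

An empty (or absent) file yields the full default configuration — the
published model settings (365 one-day cycles, cohort of 1000, GBP 20 000
threshold, 1000 PSA iterations, 1000x250 nested VOI loops) plus this
package's synthetic-trial defaults.  Unknown keys are rejected so typos
fail loudly.

The intervention cost is not published; the default prices the three-session
shockwave course as three podiatrist-led outpatient contacts at GBP 47
each (a repo default, not a published figure).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .cea import DEFAULT_THRESHOLD, SubgroupProfile, DEFAULT_SUBGROUPS
from .distributions import ParameterDistributions
from .markov import DailyTransitionParams, StateCosts, StateUtilities
from .trial import TrialConfig

__all__ = ["RunConfig", "validate_config", "load_config", "config_hash"]


@dataclass(frozen=True)
class PathsBlock:
    trial_csv: str = "results/trial.csv"
    results_dir: str = "results"


@dataclass(frozen=True)
class TogglesBlock:
    correct_event_betas: bool = True
    correct_healed_cost: bool = True
    swap_open_healed_utilities: bool = True


@dataclass(frozen=True)
class ModelBlock:
    horizon_days: int = 365
    cohort_size: int = 1000
    threshold: float = DEFAULT_THRESHOLD
    intervention_session_cost: float = 47.0
    n_sessions: int = 3
    amputation_event_cost: float = 0.0
    transition: DailyTransitionParams = field(
        default_factory=DailyTransitionParams
    )
    utilities: StateUtilities = field(default_factory=StateUtilities)
    costs: StateCosts = field(default_factory=StateCosts)
    toggles: TogglesBlock = field(default_factory=TogglesBlock)

    @property
    def intervention_cost(self) -> float:
        return self.intervention_session_cost * self.n_sessions


@dataclass(frozen=True)
class PsaBlock:
    n_iter: int = 1000


@dataclass(frozen=True)
class VoiBlock:
    inner: int = 1000
    outer: int = 250
    incidences: tuple[float, ...] = (50_000.0, 100_000.0)
    groups: tuple[str, ...] = ("high_dose_effect", "state_costs",
                               "state_utilities")


@dataclass(frozen=True)
class RunConfig:
    paths: PathsBlock = field(default_factory=PathsBlock)
    trial: TrialConfig = field(default_factory=TrialConfig)
    model: ModelBlock = field(default_factory=ModelBlock)
    psa: PsaBlock = field(default_factory=PsaBlock)
    voi: VoiBlock = field(default_factory=VoiBlock)
    subgroups: tuple[SubgroupProfile, ...] = DEFAULT_SUBGROUPS
    seed: int = 0
    log_level: str = "INFO"

    def distributions(self) -> ParameterDistributions:
        t = self.model.toggles
        return ParameterDistributions.published(
            correct_event_betas=t.correct_event_betas,
            correct_healed_cost=t.correct_healed_cost,
            swap_open_healed_utilities=t.swap_open_healed_utilities,
        )

    def to_dict(self) -> dict:
        def plain(obj: Any) -> Any:
            if isinstance(obj, Mapping):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(asdict(self))


def _build_dataclass(cls, raw: Mapping[str, Any], path: str):
    if not isinstance(raw, Mapping):
        raise ValueError(f"config section {path!r} must be a mapping")
    allowed = {f.name for f in fields(cls)}
    unknown = sorted(set(raw) - allowed)
    if unknown:
        raise ValueError(
            f"unknown config key(s) under {path!r}: {', '.join(unknown)}"
        )
    kwargs: dict[str, Any] = {}
    for f in fields(cls):
        if f.name not in raw:
            continue
        value = raw[f.name]
        nested = {
            "transition": DailyTransitionParams,
            "utilities": StateUtilities,
            "costs": StateCosts,
            "toggles": TogglesBlock,
        }
        if f.name in nested and isinstance(value, Mapping):
            value = _build_dataclass(nested[f.name], value,
                                     f"{path}.{f.name}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def validate_config(raw: Mapping[str, Any] | None) -> RunConfig:
    """Typed, range-checked configuration from a raw mapping.

    ``None`` or an empty mapping yields the full default configuration.
    Unknown keys anywhere in the tree are rejected; out-of-range
    probabilities and utilities are rejected naming the field.
    """
    raw = dict(raw or {})
    top_allowed = {"paths", "trial", "model", "psa", "voi", "subgroups",
                   "seed", "log_level"}
    unknown = sorted(set(raw) - top_allowed)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")

    paths = _build_dataclass(PathsBlock, raw.get("paths", {}), "paths")
    trial = _build_dataclass(TrialConfig, raw.get("trial", {}), "trial")
    model = _build_dataclass(ModelBlock, raw.get("model", {}), "model")
    psa = _build_dataclass(PsaBlock, raw.get("psa", {}), "psa")
    voi = _build_dataclass(VoiBlock, raw.get("voi", {}), "voi")

    subgroups_raw = raw.get("subgroups")
    if subgroups_raw is None:
        subgroups = DEFAULT_SUBGROUPS
    else:
        subgroups = tuple(
            _build_dataclass(SubgroupProfile, g, f"subgroups[{i}]")
            for i, g in enumerate(subgroups_raw)
        )

    cfg = RunConfig(
        paths=paths, trial=trial, model=model, psa=psa, voi=voi,
        subgroups=subgroups, seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )

    # range checks (each names the offending field)
    trial.validate()
    model.transition.validate()
    model.utilities.validate()
    model.costs.validate()
    if model.horizon_days < 1:
        raise ValueError("model.horizon_days must be >= 1")
    if model.cohort_size < 1:
        raise ValueError("model.cohort_size must be >= 1")
    if model.threshold < 0:
        raise ValueError("model.threshold must be >= 0")
    if model.intervention_session_cost < 0 or model.n_sessions < 0:
        raise ValueError("model intervention cost fields must be >= 0")
    if psa.n_iter < 1:
        raise ValueError("psa.n_iter must be >= 1")
    if cfg.voi.inner < 1 or cfg.voi.outer < 2:
        raise ValueError("voi.inner must be >= 1 and voi.outer >= 2")
    if any(i < 0 for i in cfg.voi.incidences):
        raise ValueError("voi.incidences must be >= 0")
    return cfg


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config file (``None`` -> defaults)."""
    if path is None:
        return validate_config({})
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    return validate_config(raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration, for run metadata."""
    canon = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def apply_overrides(cfg: RunConfig, overrides: Sequence[str]) -> RunConfig:
    """Apply ``section.key=value`` override strings to a config."""
    raw = cfg.to_dict()
    for ov in overrides:
        if "=" not in ov:
            raise ValueError(f"override {ov!r} is not of the form key=value")
        dotted, value = ov.split("=", 1)
        node: Any = raw
        parts = dotted.split(".")
        for p in parts[:-1]:
            if p not in node:
                raise ValueError(f"unknown override path {dotted!r}")
            node = node[p]
        if parts[-1] not in node:
            raise ValueError(f"unknown override path {dotted!r}")
        node[parts[-1]] = yaml.safe_load(value)
    return validate_config(raw)
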