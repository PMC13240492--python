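"""End-to-end orchestration: generate -> fit -> analyses -> tables.

Each stage writes delimited result tables plus a JSON metadata file
(stage, config hash, seed, package version) so any artifact can be
re-created from its metadata alone.  The :class:`Pipeline` caches
intermediate objects so the ``all`` run fits the survival model once.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .cea import (DecisionModel, ceac, ce_plane, deterministic_analysis,
                  run_psa, subgroup_analysis)
from .config import RunConfig, config_hash
from .markov import StateCosts
from .survival import CovariateProfile, compare_aic, fit_weibull_ph
from .trial import generate_trial, read_trial, write_trial
from .voi import evpi_curve, voi_analysis

__all__ = ["Pipeline", "run_all", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("generate", "fit", "deterministic", "psa", "subgroups", "voi")


def _round(frame: pd.DataFrame) -> pd.DataFrame:
    """Report rounding: money 2 dp, QALYs 3 dp, probabilities 3 dp."""
    out = frame.copy()
    for col in out.columns:
        low = str(col).lower()
        if out[col].dtype.kind not in "fc":
            continue
        if "qaly" in low:
            out[col] = out[col].round(3)
        elif low.startswith("p_") or "prob" in low:
            out[col] = out[col].round(3)
        elif any(key in low for key in ("cost", "nmb", "evpi", "icer")):
            out[col] = out[col].round(2)
    return out


class Pipeline:
    """Stage runner over one validated configuration."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.results_dir = Path(cfg.paths.results_dir)
        self.dataset = None
        self.fit = None
        self.model: DecisionModel | None = None
        self.psa = None

    # -- plumbing ---------------------------------------------------------

    def _write(self, name: str, frame: pd.DataFrame, stage: str,
               extra: dict | None = None) -> None:
        self.results_dir.mkdir(parents=True, exist_ok=True)
        path = self.results_dir / f"{name}.csv"
        _round(frame).to_csv(path, index=False)
        meta = {
            "stage": stage,
            "artifact": name,
            "config_hash": config_hash(self.cfg),
            "seed": self.cfg.seed,
            "package_version": __version__,
            "toggles": dataclasses.asdict(self.cfg.model.toggles),
        }
        if extra:
            meta.update(extra)
        (self.results_dir / f"{name}.meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        logger.info("wrote %s", path)

    def _ensure_dataset(self):
        if self.dataset is None:
            path = Path(self.cfg.paths.trial_csv)
            if path.exists():
                self.dataset = read_trial(path)
            else:
                self.run_generate()
        return self.dataset

    def _ensure_model(self) -> DecisionModel:
        if self.model is None:
            self.run_fit()
        return self.model

    def _ensure_psa(self):
        if self.psa is None:
            self.run_psa()
        return self.psa

    # -- stages -----------------------------------------------------------

    def run_generate(self):
        cfg = self.cfg
        trial_cfg = dataclasses.replace(cfg.trial, seed=cfg.seed)
        self.dataset = generate_trial(trial_cfg)
        path = Path(cfg.paths.trial_csv)
        path.parent.mkdir(parents=True, exist_ok=True)
        write_trial(self.dataset, path)
        self._write("trial_summary", pd.DataFrame(
            [{"n_patients": len(self.dataset),
              **{f"n_{a}": c for a, c in
                 sorted(self.dataset.arm_counts().items())},
              "n_healed": sum(r.event == "healed"
                              for r in self.dataset.records)}]
        ), "generate", extra={"trial_csv": str(path)})
        return self.dataset

    def run_fit(self):
        dataset = self._ensure_dataset()
        self.fit = fit_weibull_ph(dataset)
        frame = dataset.to_frame()
        profile = CovariateProfile(
            ulcer_age_days=float(frame["ulcer_age_days"].mean()),
            ulcer_area_cm2=float(frame["ulcer_area_cm2"].mean()),
            infected=float(frame["infected"].mean()),
        )
        mb = self.cfg.model
        self.model = DecisionModel(
            fit=self.fit,
            transition=mb.transition,
            utilities=mb.utilities,
            costs=dataclasses.replace(
                mb.costs, amputation_event_cost=mb.amputation_event_cost
            ),
            intervention_costs={
                "standard": 0.0,
                "low_dose": mb.intervention_cost,
                "high_dose": mb.intervention_cost,
            },
            profile=profile,
            horizon_days=mb.horizon_days,
            cohort_size=mb.cohort_size,
        )
        summary = self.fit.summary().reset_index(names="parameter")
        self._write("survival_fit", summary, "fit",
                    extra={"aic": self.fit.aic, "loglik": self.fit.loglik,
                           "n_events": self.fit.n_events,
                           "n_censored": self.fit.n_censored})
        self._write("survival_aic", compare_aic(dataset), "fit")
        return self.fit

    def run_deterministic(self):
        model = self._ensure_model()
        result = deterministic_analysis(model)
        self._write("deterministic", result.table.reset_index(
            names="strategy"), "deterministic")
        return result

    def run_psa(self):
        model = self._ensure_model()
        self.psa = run_psa(model, self.cfg.distributions(),
                           n_iter=self.cfg.psa.n_iter,
                           seed=self.cfg.seed + 1)
        draws = pd.concat(
            [self.psa.costs.add_prefix("cost_"),
             self.psa.qalys.add_prefix("qaly_")], axis=1
        )
        draws.insert(0, "draw", range(self.psa.n_iter))
        self._write("psa_draws", draws, "psa",
                    extra={"n_iter": self.psa.n_iter,
                           "n_redrawn": self.psa.n_redrawn})
        self._write("ceac", ceac(self.psa), "psa")
        self._write("ce_plane", ce_plane(self.psa), "psa")
        return self.psa

    def run_subgroups(self):
        model = self._ensure_model()
        table = subgroup_analysis(
            model, self.cfg.distributions(),
            profiles=self.cfg.subgroups,
            threshold=self.cfg.model.threshold,
            n_iter=self.cfg.psa.n_iter, seed=self.cfg.seed + 2,
        )
        self._write("subgroup_nmb", table, "subgroups")
        return table

    def run_voi(self):
        model = self._ensure_model()
        psa = self._ensure_psa()
        vb = self.cfg.voi
        result = voi_analysis(
            model, self.cfg.distributions(), psa,
            threshold=self.cfg.model.threshold,
            incidences=vb.incidences, groups=vb.groups,
            inner=vb.inner, outer=vb.outer, seed=self.cfg.seed + 3,
        )
        self._write("voi_summary", result.summary(), "voi",
                    extra={"inner": vb.inner, "outer": vb.outer,
                           "evppi_raw": result.evppi_raw})
        self._write("evpi_curve",
                    evpi_curve(psa, incidences=vb.incidences), "voi")
        return result

    def run_stage(self, stage: str):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; one of {STAGES}")
        t0 = time.monotonic()
        out = getattr(self, f"run_{stage}")()
        logger.info("stage %s finished in %.1fs", stage,
                    time.monotonic() - t0)
        return out

    def run_all(self) -> None:
        for stage in STAGES:
            self.run_stage(stage)


def run_all(cfg: RunConfig) -> Pipeline:
    """Run every stage in order and return the populated pipeline."""
    pipe = Pipeline(cfg)
    pipe.run_all()
    return pipe
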