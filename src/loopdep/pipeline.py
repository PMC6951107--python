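"""End-to-end pipeline: simulate -> analyze -> forgetting model -> inference.

A run is fully determined by its configuration and master seed. The pipeline
writes the trial-level CSV, per-participant dependency results, the group
summary, the independent-forgetting comparison and a manifest recording every
parameter and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ExperimentConfig
from .dependency import (
    RetrievalDependencyModel,
    dependency_for_participant,
    group_summary,
)
from .forgetting import IndependentForgettingModel
from .io import matrices_to_trials, write_manifest, write_trials
from .simulate import Cohort, GenerativeParams, simulate_cohort
from .stats import jzs_bayes_factor, one_sample_t

logger = logging.getLogger("loopdep")


@dataclass
class RunConfig:
    """Flat, serializable description of one pipeline run."""

    experiment: int = 2
    loop_type: str = "closed"
    n_sims: int = 100
    seed: int = 0
    params: GenerativeParams = field(default_factory=GenerativeParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"experiment", "loop_type", "n_sims", "seed"}
        top = {k: v for k, v in raw.items() if k in known}
        gen = {k: v for k, v in raw.items() if k not in known}
        params = GenerativeParams(**gen, seed=top.get("seed", 0))
        return cls(params=params, **top)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PipelineReport:
    config: RunConfig
    trials: pd.DataFrame
    participant_table: pd.DataFrame
    group_table: pd.DataFrame
    forgetting_table: pd.DataFrame
    tests: dict

    def hash(self) -> str:
        h = hashlib.sha256()
        for frame in (self.participant_table, self.group_table, self.forgetting_table):
            h.update(frame.round(12).to_csv(index=False).encode())
        return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineReport:
    """Execute the full pipeline for one simulated cohort."""
    exp_config = ExperimentConfig.for_experiment(config.experiment)
    params = config.params

    logger.info("simulating cohort: %s", params.to_dict())
    try:
        cohort = simulate_cohort(params, exp_config, loop_type=config.loop_type)
    except Exception as exc:  # pragma: no cover - stage tagging
        raise RuntimeError(f"[simulate] {exc}") from exc

    try:
        dep = RetrievalDependencyModel.from_cohort(cohort).fit()
    except Exception as exc:
        raise RuntimeError(f"[analyze] {exc}") from exc

    # Observed T2 accuracy targets for the forgetting model (closed-loops,
    # not-tested-at-T1 events, as in the main analysis).
    table = dep.table
    try:
        # T1 matrices restricted to the administered (tested) closed-loop events
        t1_analysis = []
        for p in cohort.participants:
            m = cohort.matrices[p].get("T1")
            if m is None:
                continue
            keep = m.events["tested_at_T1"].to_numpy(dtype=bool) & (
                m.events["loop_type"] == "closed"
            ).to_numpy(dtype=bool)
            if keep.any():
                sub = m.subset(keep)
                if sub.is_closed_only():
                    t1_analysis.append(sub)
        forgetting_table = pd.DataFrame()
        tests = {}
        if t1_analysis and exp_config.test_at_t1:
            # observed T2 accuracy and dependency on closed-loop events not
            # previously tested (the model's target and comparison values)
            t2_acc, obs_t2 = {}, {}
            for p in cohort.participants:
                m2 = cohort.matrices[p]["T2"]
                keep = (m2.events["loop_type"] == "closed").to_numpy(bool) & ~(
                    m2.events["tested_at_T1"].to_numpy(bool)
                )
                if keep.any():
                    sub = m2.subset(keep)
                    t2_acc[p] = sub.accuracy()
                    obs_t2[p] = dependency_for_participant(sub).dependency
            t1_analysis = [m for m in t1_analysis if m.participant in t2_acc]
            fm = IndependentForgettingModel(
                t1_analysis, t2_acc
            ).fit(n_sims=config.n_sims, seed=np.random.SeedSequence(config.seed).spawn(1)[0])
            forgetting_table = fm.table
            tests["t1_vs_simulated"] = fm.predicted_decrease()
            tests["observed_vs_simulated"] = fm.compare_observed(obs_t2)
            diff_obs = np.array(
                [
                    obs_t2[p] - t1d
                    for p, t1d in zip(
                        fm.table["participant"], fm.table["t1_dependency"]
                    )
                ]
            )
            tests["bf_no_decrease"] = jzs_bayes_factor(diff_obs, direction="decrease")
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"[forgetting-model] {exc}") from exc

    try:
        for session in sorted(table["session"].unique()):
            tests[f"dependency_{session}"] = one_sample_t(
                table.loc[table["session"] == session, "dependency"].to_numpy()
            )
    except Exception as exc:
        raise RuntimeError(f"[stats] {exc}") from exc

    group = group_summary(table, by=["loop_type", "session"])
    trials = cohort.to_trials()
    report = PipelineReport(
        config=config,
        trials=trials,
        participant_table=table,
        group_table=group,
        forgetting_table=forgetting_table,
        tests=tests,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trials(trials, out / "trials.csv")
        table.to_csv(out / "dependency_by_participant.csv", index=False)
        group.to_csv(out / "dependency_summary.csv", index=False)
        if not forgetting_table.empty:
            forgetting_table.to_csv(out / "forgetting_model.csv", index=False)
        write_manifest(
            out / "manifest.json",
            config=config.to_dict(),
            report_hash=report.hash(),
            tests={k: str(v) for k, v in tests.items()},
            n_trials=len(trials),
        )
        logger.info("report written to %s (hash %s)", out, report.hash()[:12])
    return report
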