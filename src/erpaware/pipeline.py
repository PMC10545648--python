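"""End-to-end orchestration: simulate -> select -> model -> summarize.

The main pipeline mirrors the primary analysis: at-threshold selection with
blocks of 16 and the liberal chance criterion, EEG-bad trials excluded,
robust hierarchical regressions of VAN and LP amplitudes (detection-only
and full-interaction formulas), and the behavioral logistic model.  All
randomness derives from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import GibbsConfig, ModelSpec, fit_behavior_model, fit_model
from .selection import SelectionConfig, apply_exclusions, center_opacity, \
    partition_and_flag
from .simulate import generate_dataset

__all__ = ["RunConfig", "select_trials", "run_analysis", "run_full"]


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 0
    n_subjects: int = 38
    n_trials: int = 420
    block_length: int = 16
    criterion: str = "liberal"
    include_bad_eeg: bool = False
    include_orientation: bool = False
    fast: bool = False
    likelihood: str = "student_t_robust"

    def selection(self) -> SelectionConfig:
        return SelectionConfig.preset(self.block_length, self.criterion,
                                      include_bad_eeg=self.include_bad_eeg)

    def sampler(self) -> GibbsConfig:
        robust = self.likelihood == "student_t_robust"
        return (GibbsConfig.fast(robust=robust) if self.fast
                else GibbsConfig(robust=robust))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def select_trials(trials: pd.DataFrame, cfg: SelectionConfig
                  ) -> tuple[pd.DataFrame, dict]:
    """Block partitioning, validity flags, opacity centering, exclusions."""
    flagged = partition_and_flag(trials, cfg)
    centered = center_opacity(flagged)
    return apply_exclusions(centered, cfg)


def run_analysis(trials: pd.DataFrame, config: RunConfig,
                 seed: int | np.random.SeedSequence | None = None) -> dict:
    """Run selection and all models on an existing trial table.

    Returns a dict with the exclusion report, per-model summary frames, and
    the behavior-model result.
    """
    ss = np.random.SeedSequence(config.seed if seed is None else seed) \
        if not isinstance(seed, np.random.SeedSequence) else seed
    analysis, report = select_trials(trials, config.selection())
    if analysis.empty:
        return {"report": report, "empty": True}

    model_seeds = ss.spawn(5)
    sampler = config.sampler()
    results: dict = {"report": report, "empty": False, "models": {}}
    jobs = [("van_detection_only", "detection_only", "van_amp", model_seeds[0]),
            ("van_full", "full_interaction", "van_amp", model_seeds[1]),
            ("lp_detection_only", "detection_only", "lp_amp", model_seeds[2]),
            ("lp_full", "full_interaction", "lp_amp", model_seeds[3])]
    for label, formula, outcome, mseed in jobs:
        spec = ModelSpec(formula_id=formula, outcome=outcome,
                         likelihood=config.likelihood,
                         include_orientation=config.include_orientation)
        fit = fit_model(analysis, spec, sampler, mseed)
        extra = (("detection_effect",) if formula == "full_interaction" else ())
        fit.summarize(extra=extra)
        results["models"][label] = fit

    behavior_seed = int(model_seeds[4].generate_state(1)[0] % (2 ** 31))
    results["behavior"] = fit_behavior_model(analysis, seed=behavior_seed)
    return results


def run_full(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate a dataset under ``config`` and analyze it.

    When ``out_dir`` is given, writes the trial table, the run config, the
    exclusion report and per-model coefficient tables there.
    """
    ss = np.random.SeedSequence(config.seed)
    sim_seed, analysis_seed = ss.spawn(2)
    trials, truth, _ = generate_dataset(
        n_subjects=config.n_subjects, n_trials=config.n_trials, seed=sim_seed)
    results = run_analysis(trials, config, analysis_seed)
    results["trials"] = trials
    results["ground_truth"] = truth

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_config.json").write_text(config.to_json())
        trials.to_csv(out / "trials.csv", index=False)
        (out / "exclusion_report.json").write_text(
            json.dumps(results["report"], indent=2))
        if not results.get("empty"):
            for label, fit in results["models"].items():
                fit.summary_frame().to_csv(out / f"model_{label}.csv", index=False)
            (out / "behavior.json").write_text(json.dumps(
                _behavior_jsonable(results["behavior"]), indent=2))
    return results


def _behavior_jsonable(behavior: dict) -> dict:
    out = dict(behavior)
    if "summaries" in out:
        out["summaries"] = {k: v.to_dict() for k, v in out["summaries"].items()}
    return out
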