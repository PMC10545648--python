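"""Synthetic ERP dataset generator.

Produces observers, staircase-driven trial sequences, and single-trial
multichannel epochs carrying the two awareness components the analysis
targets:

* a negative occipital component (VAN) at 180-280 ms whose aware-unaware
  difference is larger at the detection threshold than at the
  identification threshold, and
* a positive centro-parietal component (LP) at 350-550 ms with the same
  ordering.

Component bumps are raised cosines in time, uniform over their electrode
set and zero elsewhere, scaled so that the window mean of a noise-free
epoch equals the programmed amplitude exactly.  Noise is white Gaussian by
default (an optional 1/f mode shapes the spectrum while keeping the
per-sample SD); rare artifact epochs receive a large low-frequency drift
and are recorded with ground truth so the artifact flagger can be scored.

Default effect sizes, the catch-trial probability, the correctness table,
and the sample size mirror the study conditions this generator emulates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np
import pandas as pd

from .features import (EpochArray, VAN_ELECTRODES, LP_ELECTRODES, VAN_WINDOW,
                       LP_WINDOW, WindowSpec, baseline_correct, downsample,
                       flag_artifacts, mean_amplitude)
from .observers import ObserverParams
from .staircase import StaircaseConfig, run_session

__all__ = ["ErpGenParams", "SubjectEffects", "PopulationParams",
           "simulate_epoch", "simulate_epochs", "generate_dataset",
           "write_trials_csv", "write_epochs_hdf5", "write_ground_truth_json",
           "DEFAULT_CHANNELS"]

DEFAULT_CHANNELS: tuple[str, ...] = VAN_ELECTRODES + LP_ELECTRODES + ("Fz", "Cz")


@dataclass(frozen=True)
class ErpGenParams:
    """Parameters of the epoch generator (amplitudes in uV).

    The four effect defaults are the aware-unaware differences estimated in
    the study this generator emulates; the opacity slopes are uV per opacity
    unit (opacity on the 0-100 scale, but at-threshold trials live below ~5).
    """

    van_effect_detect: float = -2.12
    van_effect_identify: float = -0.46
    lp_effect_detect: float = 1.83
    lp_effect_identify: float = 0.43
    van_opacity_slope: float = -3.61
    lp_opacity_slope: float = 3.19
    subject_sd: float = 0.8          # between-subject SD of each effect
    intercept_sd: float = 1.0        # between-subject SD of window baselines
    noise_sd: float = 40.0           # per-sample noise SD
    noise_mode: str = "white"        # or "pink"
    artifact_rate: float = 0.03
    artifact_amp_uv: tuple[float, float] = (200.0, 400.0)
    van_window: WindowSpec = VAN_WINDOW
    lp_window: WindowSpec = LP_WINDOW
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    sample_rate: float = 512.0
    tmin_ms: float = -100.0
    tmax_ms: float = 800.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if set(self.van_window.electrodes) & set(self.lp_window.electrodes):
            raise ValueError("VAN and LP electrode sets must be disjoint")
        for w in (self.van_window, self.lp_window):
            if w.t_start < self.tmin_ms or w.t_end > self.tmax_ms:
                raise ValueError("analysis window outside the epoch span")

    def times_ms(self) -> np.ndarray:
        npre = int(round(-self.tmin_ms / 1000.0 * self.sample_rate))
        npost = int(round(self.tmax_ms / 1000.0 * self.sample_rate))
        return np.arange(-npre, npost + 1) / self.sample_rate * 1000.0

    def effect(self, component: str, staircase: str) -> float:
        return {("van", "detect"): self.van_effect_detect,
                ("van", "identify"): self.van_effect_identify,
                ("lp", "detect"): self.lp_effect_detect,
                ("lp", "identify"): self.lp_effect_identify}[(component, staircase)]


@dataclass(frozen=True)
class SubjectEffects:
    """Per-subject deviations: random slopes on each awareness effect and
    random window intercepts."""

    van_detect_dev: float = 0.0
    van_identify_dev: float = 0.0
    lp_detect_dev: float = 0.0
    lp_identify_dev: float = 0.0
    van_intercept: float = 0.0
    lp_intercept: float = 0.0

    @classmethod
    def draw(cls, params: ErpGenParams, rng: np.random.Generator) -> "SubjectEffects":
        s, i = params.subject_sd, params.intercept_sd
        return cls(*(rng.normal(0.0, s, 4)), *(rng.normal(0.0, i, 2)))

    def dev(self, component: str, staircase: str) -> float:
        return getattr(self, f"{component}_{staircase}_dev")

    def intercept(self, component: str) -> float:
        return getattr(self, f"{component}_intercept")


def _bump_shape(times_ms: np.ndarray, window: WindowSpec) -> np.ndarray:
    """Raised cosine supported on the window, normalized so its mean over
    the window's (inclusive) samples is 1."""
    mask = (times_ms >= window.t_start) & (times_ms <= window.t_end)
    shape = np.zeros_like(times_ms)
    phase = (times_ms[mask] - window.t_start) / (window.t_end - window.t_start)
    vals = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    shape[mask] = vals / vals.mean()
    return shape


def _noise(params: ErpGenParams, shape: tuple, rng: np.random.Generator) -> np.ndarray:
    white = rng.normal(0.0, params.noise_sd, shape)
    if params.noise_mode == "white":
        return white
    if params.noise_mode != "pink":
        raise ValueError(f"unknown noise_mode {params.noise_mode!r}")
    # shape the spectrum as 1/f, then rescale to the requested per-sample SD
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1], d=1.0 / params.sample_rate)
    f[0] = f[1]
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n=shape[-1], axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd * params.noise_sd


def _component_amplitude(params: ErpGenParams, component: str, staircase: str,
                         aware: int, opacity_centered: float,
                         effects: SubjectEffects) -> float:
    slope = params.van_opacity_slope if component == "van" else params.lp_opacity_slope
    amp = effects.intercept(component) + opacity_centered * slope
    if aware:
        amp += params.effect(component, staircase) + effects.dev(component, staircase)
    return amp


def simulate_epochs(params: ErpGenParams, trials: pd.DataFrame,
                    effects: SubjectEffects,
                    rng: np.random.Generator) -> tuple[EpochArray, np.ndarray]:
    """Generate one epoch per trial row.

    Each trial needs ``staircase``, ``aware`` and ``opacity_centered``
    (catch trials get no components).  Returns the epoch stack and the
    ground-truth artifact indicator per epoch.
    """
    times = params.times_ms()
    n_ch, n_t = len(params.channels), times.size
    n = len(trials)
    data = _noise(params, (n, n_ch, n_t), rng)

    shapes = {"van": _bump_shape(times, params.van_window),
              "lp": _bump_shape(times, params.lp_window)}
    chans = {"van": [params.channels.index(c) for c in params.van_window.electrodes],
             "lp": [params.channels.index(c) for c in params.lp_window.electrodes]}

    artifact = rng.random(n) < params.artifact_rate
    lo, hi = params.artifact_amp_uv
    t_s = times / 1000.0
    for i, row in enumerate(trials.itertuples(index=False)):
        sc = row.staircase
        if sc in ("detect", "identify"):
            aware = int(row.aware)
            oc = float(row.opacity_centered)
            for comp in ("van", "lp"):
                amp = _component_amplitude(params, comp, sc, aware, oc, effects)
                if amp != 0.0:
                    data[i, chans[comp], :] += amp * shapes[comp]
        if artifact[i]:
            amp = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
            freq = rng.uniform(0.5, 1.5)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            data[i, :, :] += amp * np.sin(2.0 * np.pi * freq * t_s + phase)

    return EpochArray(data, params.channels, times, params.sample_rate), artifact


def simulate_epoch(params: ErpGenParams, trial: pd.Series | dict,
                   effects: SubjectEffects,
                   rng: np.random.Generator) -> EpochArray:
    """Single-trial convenience wrapper around :func:`simulate_epochs`."""
    df = pd.DataFrame([dict(trial)])
    epochs, _ = simulate_epochs(params, df, effects, rng)
    return epochs


@dataclass(frozen=True)
class PopulationParams:
    """Between-subject distribution of observer parameters.

    Threshold means/SDs are calibrated to the condition-wise opacity means
    of the emulated study (detection ~1, identification ~2.9 on the 0-100
    scale, with the printed between-subject spreads)."""

    mu_detect_mean: float = 1.05
    mu_detect_sd: float = 0.30
    mu_identify_mean: float = 2.85
    mu_identify_sd: float = 1.00
    sigma_detect: float = 0.30
    sigma_identify: float = 0.60
    false_alarm_rate: float = 0.04
    lapse_rate: float = 0.02

    def draw_observer(self, rng: np.random.Generator) -> ObserverParams:
        mu_d = max(0.3, rng.normal(self.mu_detect_mean, self.mu_detect_sd))
        mu_i = max(mu_d + 0.5, rng.normal(self.mu_identify_mean, self.mu_identify_sd))
        return ObserverParams(mu_detect=mu_d, sigma_detect=self.sigma_detect,
                              mu_identify=mu_i, sigma_identify=self.sigma_identify,
                              false_alarm_rate=self.false_alarm_rate,
                              lapse_rate=self.lapse_rate)


def _default_staircase_cfgs(rule: str) -> tuple[StaircaseConfig, StaircaseConfig]:
    detect = StaircaseConfig(rule=rule, initial_opacity=4.0, initial_step=0.8,
                             resolution=500)
    identify = StaircaseConfig(rule=rule, initial_opacity=8.0, initial_step=1.2,
                               resolution=500)
    return detect, identify


def generate_dataset(n_subjects: int = 38, n_trials: int = 420,
                     erp_params: ErpGenParams | None = None,
                     population: PopulationParams | None = None,
                     catch_prob: float = 0.05,
                     staircase_rule: str = "two_up_two_down",
                     downsample_factor: int = 2,
                     seed: int | np.random.SeedSequence = 0,
                     keep_epochs: bool = False,
                     epochs_path: str | None = None,
                     ) -> tuple[pd.DataFrame, dict, EpochArray | None]:
    """Simulate a full multi-subject experiment and extract trial features.

    Per subject: draw an observer and ERP effect deviations, run two
    interleaved staircases with catch trials, simulate one epoch per trial,
    then push the epochs through the measurement path (baseline correction,
    anti-aliased downsampling, window means, artifact flagging) to fill the
    ``van_amp`` / ``lp_amp`` / ``eeg_bad`` columns.  The ground-truth record
    stores every generating parameter, so expected condition means are
    recomputable analytically.  Identical seeds give bit-identical outputs.

    Returns ``(trial_table, ground_truth, epochs)``; ``epochs`` is None
    unless ``keep_epochs`` (memory) — ``epochs_path`` streams them to HDF5
    either way.
    """
    if n_subjects < 1 or n_trials < 1:
        raise ValueError("n_subjects and n_trials must be >= 1")
    erp_params = ErpGenParams() if erp_params is None else erp_params
    population = PopulationParams() if population is None else population
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    subject_seeds = ss.spawn(n_subjects)
    detect_cfg, identify_cfg = _default_staircase_cfgs(staircase_rule)

    frames, kept, truth_subjects = [], [], {}
    h5 = None
    try:
        for s in range(n_subjects):
            rng = np.random.default_rng(subject_seeds[s])
            observer = population.draw_observer(rng)
            effects = SubjectEffects.draw(erp_params, rng)
            trials = run_session(detect_cfg, identify_cfg, observer, n_trials,
                                 catch_prob=catch_prob, rng=rng, subject_id=s)
            # generation-time opacity reference: the subject's generating
            # threshold (analysis later re-centers per block)
            mu = {"detect": observer.mu_detect, "identify": observer.mu_identify,
                  "catch": 0.0}
            trials["opacity_centered"] = [
                row.opacity - mu[row.staircase] if row.staircase != "catch" else 0.0
                for row in trials.itertuples(index=False)]

            epochs, artifact = simulate_epochs(erp_params, trials, effects, rng)
            corrected = baseline_correct(epochs)
            bad = flag_artifacts(corrected)
            measured = (downsample(corrected, downsample_factor)
                        if downsample_factor > 1 else corrected)
            trials["van_amp"] = mean_amplitude(measured, erp_params.van_window)
            trials["lp_amp"] = mean_amplitude(measured, erp_params.lp_window)
            trials["eeg_bad"] = bad
            trials["artifact_true"] = artifact
            frames.append(trials)
            truth_subjects[str(s)] = {
                "observer": {k: v for k, v in asdict(observer).items()
                             if k != "correct_prob"},
                "effects": asdict(effects),
            }
            if epochs_path is not None:
                if h5 is None:
                    h5 = h5py.File(epochs_path, "w")
                    h5.create_dataset("channels",
                                      data=np.array(epochs.channels, dtype="S"))
                    h5.create_dataset("times_ms", data=epochs.times_ms)
                    h5.attrs["sample_rate"] = epochs.sample_rate
                    h5.create_dataset(
                        "epochs", shape=(0,) + epochs.data.shape[1:],
                        maxshape=(None,) + epochs.data.shape[1:],
                        dtype="f4", chunks=(64,) + epochs.data.shape[1:])
                d = h5["epochs"]
                d.resize(d.shape[0] + epochs.data.shape[0], axis=0)
                d[-epochs.data.shape[0]:] = epochs.data.astype("f4")
            if keep_epochs:
                kept.append(epochs)
    finally:
        if h5 is not None:
            h5.close()

    table = pd.concat(frames, ignore_index=True)
    ground_truth = {
        "seed": ss.entropy,
        "n_subjects": n_subjects, "n_trials": n_trials,
        "catch_prob": catch_prob, "staircase_rule": staircase_rule,
        "downsample_factor": downsample_factor,
        "erp_params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(erp_params).items()
                       if k not in ("van_window", "lp_window")},
        "population": asdict(population),
        "correct_prob": {f"{c}_pas{r}": p for (c, r), p
                         in ObserverParams().correct_prob.items()},
        "subjects": truth_subjects,
    }
    all_epochs = None
    if keep_epochs:
        all_epochs = EpochArray(np.concatenate([e.data for e in kept], axis=0),
                                kept[0].channels, kept[0].times_ms,
                                kept[0].sample_rate)
    return table, ground_truth, all_epochs


def write_trials_csv(trials: pd.DataFrame, path: str) -> None:
    trials.to_csv(path, index=False)


def write_epochs_hdf5(epochs: EpochArray, path: str) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("epochs", data=epochs.data.astype("f4"))
        h5.create_dataset("channels", data=np.array(epochs.channels, dtype="S"))
        h5.create_dataset("times_ms", data=epochs.times_ms)
        h5.attrs["sample_rate"] = epochs.sample_rate


def write_ground_truth_json(ground_truth: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(ground_truth, fh, indent=2, default=str)
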