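"""Adaptive up-down staircases tracking awareness thresholds.

Two interleaved staircases adjust stimulus opacity trial by trial so that
awareness reports hover around 50%: one tracks the detection threshold
(PAS2 vs PAS1), the other the identification threshold (PAS3 vs PAS2).
Both the 1-up-1-down rule (move after every response) and the 2-up-2-down
rule (move only after two consecutive identical responses) target the 50%
point of the underlying psychometric function.  Step size shrinks after
every second reversal, and opacity lives on a discrete software grid whose
resolution is configurable; a luminance map can recode grid levels that are
physically indistinguishable on screen to their class-mean opacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .observers import ObserverParams, observer_respond, observer_report_orientation

__all__ = ["StaircaseConfig", "StaircaseState", "LuminanceMap",
           "update", "run_session", "recode_opacity", "aware_from_pas"]


@dataclass(frozen=True)
class StaircaseConfig:
    """Configuration of one adaptive staircase.

    ``resolution`` is the number of representable steps between 0 and 1 on
    the software opacity scale, so the grid spacing on the 0-100 scale is
    ``100 / resolution``.  ``min_step`` defaults to one grid unit.
    """

    rule: str = "one_up_one_down"            # or "two_up_two_down"
    initial_opacity: float = 5.0
    initial_step: float = 0.8
    step_shrink_factor: float = 0.5
    resolution: int = 500
    min_step: float | None = None
    bounds: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if self.rule not in ("one_up_one_down", "two_up_two_down"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if not 0.0 < self.step_shrink_factor <= 1.0:
            raise ValueError("step_shrink_factor must be in (0, 1]")
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")
        lo, hi = self.bounds
        if not lo <= self.initial_opacity <= hi:
            raise ValueError("initial_opacity outside bounds")

    @property
    def grid_step(self) -> float:
        return (self.bounds[1] - self.bounds[0]) / self.resolution

    @property
    def effective_min_step(self) -> float:
        return self.grid_step if self.min_step is None else self.min_step


@dataclass
class StaircaseState:
    """Mutable state of a running staircase."""

    opacity: float
    step: float
    n_reversals: int = 0
    last_direction: str = "none"             # "up" | "down" | "none"
    consecutive_same_responses: int = 0
    last_response: int | None = None         # aware flag of previous trial
    history: list[tuple[float, int]] = field(default_factory=list)

    @classmethod
    def from_config(cls, cfg: StaircaseConfig) -> "StaircaseState":
        return cls(opacity=cfg.initial_opacity, step=cfg.initial_step)


def _snap(value: float, old: float, direction: str, cfg: StaircaseConfig) -> float:
    """Clamp to bounds and snap to the opacity grid.

    Rounds to the nearest grid level but never snaps back onto the previous
    level when a move was requested: a requested move always advances at
    least one grid unit in its direction (unless blocked by a bound).  This
    prevents the staircase from locking between two adjacent levels when the
    step has shrunk below half a grid unit.
    """
    lo, hi = cfg.bounds
    g = cfg.grid_step
    value = min(max(value, lo), hi)
    k = round((value - lo) / g)
    snapped = lo + k * g
    if direction != "none" and abs(snapped - old) < g / 2:
        snapped = old + (g if direction == "up" else -g)
        snapped = min(max(snapped, lo), hi)
    return snapped


def update(state: StaircaseState, cfg: StaircaseConfig, aware: int) -> StaircaseState:
    """Advance the staircase by one response; returns a new state.

    Unaware responses drive opacity up, aware responses drive it down.  Under
    ``two_up_two_down`` a move happens only after two consecutive identical
    responses, and the run counter resets after each move.  A change of
    movement direction counts as a reversal; after every second reversal the
    step is multiplied by ``step_shrink_factor`` (floored at ``min_step``).
    """
    aware = int(aware)
    direction = "down" if aware else "up"

    if cfg.rule == "one_up_one_down":
        move = True
        run = 0
    else:
        run = state.consecutive_same_responses + 1 if aware == state.last_response else 1
        move = run >= 2
        if move:
            run = 0

    new = replace(state)
    new.history = state.history + [(state.opacity, aware)]
    new.consecutive_same_responses = run
    new.last_response = aware
    if not move:
        return new

    step = state.step
    n_rev = state.n_reversals
    if state.last_direction != "none" and direction != state.last_direction:
        n_rev += 1
        if n_rev % 2 == 0:
            step = max(cfg.effective_min_step, step * cfg.step_shrink_factor)

    delta = step if direction == "up" else -step
    new.opacity = _snap(state.opacity + delta, state.opacity, direction, cfg)
    new.step = step
    new.n_reversals = n_rev
    new.last_direction = direction
    return new


def aware_from_pas(staircase: str, pas: int) -> int:
    """Dummy-code awareness from the PAS rating, per staircase.

    Detection: PAS >= 2 is aware.  Identification: PAS = 3 is aware.
    """
    if staircase == "detect":
        return int(pas >= 2)
    if staircase == "identify":
        return int(pas == 3)
    raise ValueError(f"no awareness coding for staircase {staircase!r}")


def run_session(detect_cfg: StaircaseConfig, identify_cfg: StaircaseConfig,
                observer: ObserverParams, n_trials: int,
                catch_prob: float = 0.05,
                rng: np.random.Generator | None = None,
                subject_id: int = 0) -> pd.DataFrame:
    """Simulate one experimental session with two interleaved staircases.

    Each trial is a catch trial (opacity 0, no grating) with probability
    ``catch_prob``, otherwise it is assigned to the detection or the
    identification staircase with equal probability and a random +/-45 deg
    orientation.  Each staircase updates only from its own trials.  Returns
    a tidy trial table with one row per trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    states = {"detect": StaircaseState.from_config(detect_cfg),
              "identify": StaircaseState.from_config(identify_cfg)}
    cfgs = {"detect": detect_cfg, "identify": identify_cfg}

    rows = []
    for t in range(n_trials):
        if rng.random() < catch_prob:
            pas = observer_respond(observer, "catch", 0.0, rng)
            rows.append(dict(subject_id=subject_id, trial_index=t,
                             staircase="catch", opacity=0.0,
                             orientation="none", pas=pas,
                             aware=np.nan, threshold_dummy=np.nan,
                             correct=np.nan))
            continue
        sc = "detect" if rng.random() < 0.5 else "identify"
        orientation = "left" if rng.random() < 0.5 else "right"
        state = states[sc]
        opacity = state.opacity
        pas = observer_respond(observer, sc, opacity, rng)
        aware = aware_from_pas(sc, pas)
        _, correct = observer_report_orientation(observer, sc, pas, orientation, rng)
        states[sc] = update(state, cfgs[sc], aware)
        rows.append(dict(subject_id=subject_id, trial_index=t, staircase=sc,
                         opacity=opacity, orientation=orientation, pas=pas,
                         aware=aware,
                         threshold_dummy=1 if sc == "detect" else 0,
                         correct=correct))
    return pd.DataFrame(rows)


class LuminanceMap:
    """Recode opacity levels whose on-screen luminance is indistinguishable.

    The display hardware cannot resolve arbitrarily fine opacity steps:
    ranges of software levels that produce the same measured luminance form
    equivalence classes, and every level in a class is represented by the
    class-mean opacity.
    """

    def __init__(self, classes: list[list[float]]):
        seen: set[float] = set()
        self._mean: dict[float, float] = {}
        for cls in classes:
            if not cls:
                raise ValueError("empty equivalence class")
            m = float(np.mean(cls))
            lo, hi = min(cls), max(cls)
            if not lo <= m <= hi:      # pragma: no cover - arithmetic guard
                raise ValueError("class mean outside class span")
            for level in cls:
                if level in seen:
                    raise ValueError(f"level {level} in two classes")
                seen.add(level)
                self._mean[level] = m
        # class means map to themselves so recoding is idempotent
        for m in list(self._mean.values()):
            self._mean.setdefault(m, m)

    @classmethod
    def identity(cls, levels: list[float]) -> "LuminanceMap":
        return cls([[lv] for lv in levels])

    @classmethod
    def from_quantization(cls, levels: list[float],
                          luminance_step: float) -> "LuminanceMap":
        """Group sorted levels whose luminance (proportional to opacity here)
        falls in the same quantization bin of width ``luminance_step``."""
        groups: dict[int, list[float]] = {}
        for lv in sorted(levels):
            groups.setdefault(int(np.floor(lv / luminance_step)), []).append(lv)
        return cls(list(groups.values()))

    def recode(self, level: float) -> float:
        try:
            return self._mean[level]
        except KeyError:
            raise ValueError(f"opacity level {level} not covered by the map") from None


def recode_opacity(levels, lum_map: LuminanceMap):
    """Replace each opacity level by its luminance-class mean (idempotent
    when the class means are themselves representable levels)."""
    arr = np.asarray(levels, dtype=float)
    return np.array([lum_map.recode(v) for v in arr.ravel()]).reshape(arr.shape)
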