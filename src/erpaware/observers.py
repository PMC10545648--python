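"""Generative observer model for threshold-tracked awareness experiments.

An observer rates each stimulus on a three-level perceptual awareness scale
(PAS): 1 = nothing, 2 = something, 3 = clear orientation.  Two probit
psychometric functions govern the ratings as a function of stimulus opacity
(0 = transparent .. 100 = opaque):

* the *detection* function gives ``P(PAS >= 2)``, crossing 0.5 at
  ``mu_detect``;
* the *identification* function gives ``P(PAS = 3)``, crossing 0.5 at
  ``mu_identify``.

A false-alarm floor lifts ``P(PAS >= 2)`` at opacity 0, and a lapse
parameter replaces the rating with a uniform draw on {1, 2, 3} on a small
fraction of trials.  Orientation reports are generated from a condition- and
rating-specific correctness table rather than from a full signal-detection
model: only the correctness probabilities enter the downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import norm

__all__ = ["ObserverParams", "observer_respond", "observer_report_orientation",
           "DEFAULT_CORRECT_PROB"]

#: Probability of a correct orientation report by (staircase condition, PAS
#: rating).  Values are the condition means reported for this paradigm:
#: chance-level performance below the detection threshold, near-ceiling for
#: clearly identified stimuli.
DEFAULT_CORRECT_PROB: dict[tuple[str, int], float] = {
    ("detect", 1): 0.51,
    ("detect", 2): 0.53,
    ("identify", 2): 0.72,
    ("identify", 3): 0.97,
    # ratings a staircase's awareness coding does not target can still
    # occur: chance when nothing is experienced, ceiling when the
    # orientation is clearly seen
    ("identify", 1): 0.50,
    ("detect", 3): 0.97,
}


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of a simulated observer.

    Parameters
    ----------
    mu_detect
        Opacity (0-100) at which ``P(PAS >= 2) = 0.5`` (detection threshold).
    sigma_detect
        Scale (opacity units) of the detection probit.
    mu_identify
        Opacity at which ``P(PAS = 3) = 0.5`` (identification threshold).
    sigma_identify
        Scale of the identification probit.
    false_alarm_rate
        Probability of reporting PAS >= 2 at opacity 0.
    lapse_rate
        Probability that the rating is uniformly random on {1, 2, 3}.
    correct_prob
        Map (condition, rating) -> probability of a correct orientation
        report.
    """

    mu_detect: float = 1.05
    sigma_detect: float = 0.30
    mu_identify: float = 2.85
    sigma_identify: float = 0.60
    false_alarm_rate: float = 0.04
    lapse_rate: float = 0.02
    correct_prob: Mapping[tuple[str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_CORRECT_PROB))

    def __post_init__(self) -> None:
        if not self.mu_identify > self.mu_detect:
            raise ValueError("mu_identify must exceed mu_detect")
        if self.sigma_detect <= 0 or self.sigma_identify <= 0:
            raise ValueError("probit scales must be positive")
        for name in ("false_alarm_rate", "lapse_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.2:
                raise ValueError(f"{name} must lie in [0, 0.2], got {v}")
        for key, p in self.correct_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"correct_prob[{key}] = {p} outside [0, 1]")

    def p_pas_ge2(self, opacity: float | np.ndarray) -> float | np.ndarray:
        """``P(PAS >= 2)`` at the given opacity (lapse excluded)."""
        fa = self.false_alarm_rate
        return fa + (1.0 - fa) * norm.cdf(
            (np.asarray(opacity, dtype=float) - self.mu_detect) / self.sigma_detect)

    def p_pas3(self, opacity: float | np.ndarray) -> float | np.ndarray:
        """``P(PAS = 3)``, capped so the ordered-response structure holds."""
        p3 = norm.cdf(
            (np.asarray(opacity, dtype=float) - self.mu_identify) / self.sigma_identify)
        return np.minimum(self.p_pas_ge2(opacity), p3)


def _check_opacity(opacity: float) -> None:
    if not 0.0 <= opacity <= 100.0:
        raise ValueError(f"opacity {opacity} outside [0, 100]")


def observer_respond(obs: ObserverParams, staircase: str, opacity: float,
                     rng: np.random.Generator) -> int:
    """Draw a PAS rating (1, 2 or 3) for one stimulus presentation.

    The rating is sampled from the ordered two-probit model; with probability
    ``obs.lapse_rate`` it is replaced by a uniform draw.  ``staircase`` is
    carried for interface symmetry (the response model does not depend on
    which staircase presented the stimulus).
    """
    _check_opacity(opacity)
    if rng.random() < obs.lapse_rate:
        return int(rng.integers(1, 4))
    p_ge2 = float(obs.p_pas_ge2(opacity))
    p3 = float(obs.p_pas3(opacity))
    u = rng.random()
    if u < p3:
        return 3
    if u < p_ge2:
        return 2
    return 1


def observer_report_orientation(obs: ObserverParams, staircase: str, pas: int,
                                true_orientation: str,
                                rng: np.random.Generator) -> tuple[str, int]:
    """Simulate the forced-choice orientation report for one trial.

    Returns ``(reported_orientation, correct)``.  The report is correct with
    probability ``correct_prob[(staircase, pas)]``; otherwise the opposite
    orientation is reported.
    """
    if staircase == "catch":
        raise ValueError("catch trials have no orientation to report")
    key = (staircase, pas)
    if key not in obs.correct_prob:
        raise KeyError(f"no correct_prob entry for {key}")
    p = obs.correct_prob[key]
    correct = int(rng.random() < p)
    if correct:
        reported = true_orientation
    else:
        reported = "right" if true_orientation == "left" else "left"
    return reported, correct
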