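"""Translate a survival-efficacy trial design into CEA power inputs.

Phase III oncology designs are specified by a control-arm survival
probability at a landmark time, a target hazard ratio, error rates and the
planned numbers of patients and events.  Under exponential survival those
quantities imply the incremental effectiveness (difference of mean survival
times), a pooled effectiveness SD, and the event ratio pi = n_e/d_e that
the sample-size formula uses to account for censoring.

How to collapse the two exponential arm SDs (1/theta_0 and 1/theta_1) into
the single common sigma_E of the pooled variance formula is genuinely
underdetermined; the default here is root-mean-square pooling, which
preserves the average variance, with the control-arm SD exposed as an
alternative.  This module is a reconstruction of common design practice,
not a calibrated fit to any published figure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .trial_params import ParameterError, _require

__all__ = [
    "TrialDesign",
    "DesignInputs",
    "event_ratio_pi",
    "exponential_rate_from_landmark",
    "effectiveness_inputs_from_design",
]


@dataclass(frozen=True)
class TrialDesign:
    """Efficacy design of a two-arm survival trial.

    ``control_survival`` is the control-arm survival probability at
    ``landmark_time`` (years); ``hazard_ratio`` is experimental over
    control; ``n_expected``/``d_expected`` are the planned total sample
    size and number of events that trigger the final analysis.
    """

    control_survival: float
    landmark_time: float
    hazard_ratio: float
    alpha: float = 0.05
    target_power: float = 0.80
    n_expected: int = 0
    d_expected: int = 0

    def __post_init__(self) -> None:
        _require(0 < self.control_survival < 1, "control_survival", self.control_survival)
        _require(self.landmark_time > 0, "landmark_time", self.landmark_time)
        _require(self.hazard_ratio > 0, "hazard_ratio", self.hazard_ratio)
        _require(0 < self.alpha < 0.5, "alpha", self.alpha)
        _require(0 < self.target_power < 1, "target_power", self.target_power)
        _require(
            self.d_expected <= self.n_expected, "d_expected", self.d_expected
        )


@dataclass(frozen=True)
class DesignInputs:
    """CEA power inputs implied by an efficacy design."""

    delta_e: float
    sd_effect: float
    pi: float


def event_ratio_pi(n_expected: int, d_expected: int) -> float:
    """Event ratio pi = n_e / d_e (planned sample size over planned events).

    E.g. 500 patients with analysis at 400 events gives pi = 1.25.
    """
    if d_expected <= 0:
        raise ParameterError(f"invalid d_expected: {d_expected!r}")
    if d_expected > n_expected:
        raise ParameterError(
            f"invalid d_expected: {d_expected!r} exceeds n_expected {n_expected!r}"
        )
    return n_expected / d_expected


def exponential_rate_from_landmark(
    control_survival: float, landmark_time: float
) -> float:
    """Exponential hazard theta = -ln(S(t*)) / t* from a landmark survival."""
    if not 0 < control_survival < 1:
        raise ParameterError(f"invalid control_survival: {control_survival!r}")
    if landmark_time <= 0:
        raise ParameterError(f"invalid landmark_time: {landmark_time!r}")
    return -math.log(control_survival) / landmark_time


def effectiveness_inputs_from_design(
    design: TrialDesign,
    pooling: Literal["rms", "control"] = "rms",
) -> DesignInputs:
    """Incremental effectiveness, pooled SD and event ratio from a design.

    With exponential marginals at rates theta_0 (control, from the landmark
    survival) and theta_1 = HR * theta_0, the mean survival times are
    1/theta_j, so delta_e = 1/theta_1 - 1/theta_0 (negative when HR > 1).
    The arm SDs equal the means; ``pooling`` collapses them into the common
    sigma_E: root-mean-square (default) or the control-arm SD alone.
    """
    theta0 = exponential_rate_from_landmark(
        design.control_survival, design.landmark_time
    )
    theta1 = design.hazard_ratio * theta0
    delta_e = 1.0 / theta1 - 1.0 / theta0
    sd0, sd1 = 1.0 / theta0, 1.0 / theta1
    if pooling == "rms":
        sd_effect = math.sqrt((sd0**2 + sd1**2) / 2.0)
    elif pooling == "control":
        sd_effect = sd0
    else:
        raise ParameterError(f"invalid pooling: {pooling!r}")
    pi = (
        event_ratio_pi(design.n_expected, design.d_expected)
        if design.d_expected > 0
        else 1.0
    )
    return DesignInputs(delta_e=delta_e, sd_effect=sd_effect, pi=pi)
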