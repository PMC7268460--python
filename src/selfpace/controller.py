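"""Once-per-footstep belt-speed control law.

At every accepted footstep the target belt speed is set from the step-mean
belt speed and the step-mean state estimates:

    v_tm_tgt = vbar_tm + G_v * vbar_KF + G_p * (pbar_KF - p_0)

Although the gains enter with plus signs this is negative feedback: belt
speed and walker speed/position are measured in opposite directions in the
lab frame, so a walker drifting forward (or walking faster than the belt)
speeds the belt up, carrying the walker back toward the baseline position
``p_0``.  With ``G_v = 1`` the belt would match the estimated walking speed
exactly and with ``G_p = 1`` it would return the walker to ``p_0`` within
one second; such high gains feel abrupt to walk on, so the defaults are the
softer ``G_v = 0.25`` and ``G_p = 0.1``.

The commanded acceleration reaches the target speed in a fixed time
comparable to one step:

    a_tm_tgt = (v_tm_tgt - vbar_tm) / dt_tgt,        dt_tgt = 0.5 s

Commands are clamped to a safe speed range (the belt never reverses) and
acceleration magnitude.  Rejected steps (belt crossovers) issue no command;
the belt simply continues executing the previous one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .estimator import StepResult
from .forceplate import ConfigurationError, DataError


@dataclass(frozen=True)
class ControllerParams:
    """Gains, clamps and baseline of the speed controller."""

    g_v: float = 0.25        # speed-matching gain (dimensionless)
    g_p: float = 0.1         # recentering gain (1/s)
    dt_tgt: float = 0.5      # s, time in which to reach the target speed
    p0: float = 0.0          # m, baseline walker position
    v_min: float = 0.0       # m/s, the belt never reverses
    v_max: float = 2.5       # m/s
    a_max: float = 2.0       # m/s^2, acceleration magnitude clamp
    v_start: float = 0.8     # m/s, initial belt speed of a self-paced trial

    def __post_init__(self):
        if self.g_v < 0 or self.g_p < 0:
            raise ConfigurationError("gains must be non-negative")
        if not self.v_min <= self.v_start <= self.v_max:
            raise ConfigurationError("require v_min <= v_start <= v_max")


@dataclass(frozen=True)
class TreadmillCommand:
    """One belt-speed command, issued at a foot contact."""

    t_issue: float
    v_tgt: float
    a_tgt: float


def target_speed(vbar_tm: float, vbar_kf: float, pbar_kf: float,
                 params: ControllerParams) -> float:
    """Target belt speed, clamped to ``[v_min, v_max]``."""
    v = vbar_tm + params.g_v * vbar_kf + params.g_p * (pbar_kf - params.p0)
    return float(np.clip(v, params.v_min, params.v_max))


def target_accel(v_tgt: float, vbar_tm: float,
                 params: ControllerParams) -> float:
    """Belt acceleration reaching ``v_tgt`` in ``dt_tgt`` seconds, clamped."""
    a = (v_tgt - vbar_tm) / params.dt_tgt
    return float(np.clip(a, -params.a_max, params.a_max))


def calibrate_p0(position_log: np.ndarray) -> float:
    """Baseline position: mean estimated position over a fixed-speed window.

    The controller regulates the walker's *measured* position (referenced to
    foot placements), so the baseline must be calibrated in the same
    measure, typically during the fixed-speed portion of familiarization.
    """
    position_log = np.asarray(position_log, float)
    if position_log.size == 0:
        raise DataError("empty calibration window")
    return float(np.mean(position_log))


def update_on_contact(step: StepResult,
                      params: ControllerParams) -> Optional[TreadmillCommand]:
    """Command for one processed contact, or None.

    Only accepted steps (those whose measurement update was applied)
    generate a command; crossover steps leave the belt running the prior
    command because their step-mean state is unreliable.
    """
    if step.meas is None or not step.meas.accepted:
        return None
    v_tgt = target_speed(step.meas.vbar_tm, step.vbar_kf, step.pbar_kf,
                         params)
    a_tgt = target_accel(v_tgt, step.meas.vbar_tm, params)
    return TreadmillCommand(t_issue=step.event.t_contact,
                            v_tgt=v_tgt, a_tgt=a_tgt)
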