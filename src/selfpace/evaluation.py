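"""Quantitative evaluation of estimator accuracy and self-paced trials.

Covers the study-style outcome measures:

* step-wise RMS differences between estimated and reference step means
  (``RMS_vbar`` for speed; ``RMS_pbar`` for position after removing the
  per-trial mean offset, because the foot-placement-referenced position
  measure tracks the body only up to a constant);
* convergence time / distance: when the walking speed first enters the
  band mean +/- 1 SD of the trial's terminal segment (last 20% of time, or
  last 30 m of distance);
* mean walking speed over fixed-length distance sections;
* least-squares linear fit ``y ~ b1 x + b0`` with Pearson correlation, as
  used to compare walking-speed tests against a reference test;
* intra-subject standard deviation of repeated speed measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .forceplate import DataError
from .trial import TrialLog

#: widening applied to a degenerate (zero-SD) convergence band, m/s
BAND_EPSILON = 1e-3


@dataclass
class EvalReport:
    """Container for the evaluation outcomes of one analysis."""

    rms_vbar: Optional[float] = None     # m/s
    rms_pbar: Optional[float] = None     # m, offset-corrected
    step_errors: Optional[pd.DataFrame] = None
    t_cnvg: Optional[float] = None       # s
    d_cnvg: Optional[float] = None       # m
    fit: Optional[tuple] = None          # (b1, b0, R, p)
    sd_intra: Optional[pd.Series] = None
    section_speeds: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        out = {}
        for key in ("rms_vbar", "rms_pbar", "t_cnvg", "d_cnvg"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        if self.fit is not None:
            out.update(zip(("b1", "b0", "R", "p"), self.fit))
        if self.sd_intra is not None:
            out["sd_intra_mean"] = float(np.mean(self.sd_intra))
        if self.section_speeds is not None:
            for i, v in enumerate(self.section_speeds):
                out[f"section_{i + 1}"] = float(v)
        return out


def rms_step_errors(est_v: Sequence[float], est_p: Sequence[float],
                    ref_v: Sequence[float], ref_p: Sequence[float]) -> tuple:
    """Step-wise RMS speed and offset-corrected position differences.

    Inputs are per-step mean speeds and positions from the estimator and
    from the reference (ground truth or motion capture), aligned
    step-for-step.  The position series are offset-corrected by removing
    the mean difference over the trial before the RMS is taken.
    """
    est_v = np.asarray(est_v, float)
    est_p = np.asarray(est_p, float)
    ref_v = np.asarray(ref_v, float)
    ref_p = np.asarray(ref_p, float)
    if not est_v.shape == ref_v.shape == est_p.shape == ref_p.shape:
        raise DataError("step tables are not aligned")
    if est_v.size == 0:
        raise DataError("empty step tables")
    dv = est_v - ref_v
    dp = est_p - ref_p
    dp = dp - np.mean(dp)
    return float(np.sqrt(np.mean(dv ** 2))), float(np.sqrt(np.mean(dp ** 2)))


def _entry_time(t: np.ndarray, v: np.ndarray, lo: float, hi: float) -> float:
    inside = (v >= lo) & (v <= hi)
    idx = np.argmax(inside)
    if not inside[idx]:
        return float(t[-1])
    return float(t[idx])


def convergence_time(t: np.ndarray, v: np.ndarray,
                     duration: Optional[float] = None,
                     tail_frac: float = 0.2,
                     eps: float = BAND_EPSILON) -> float:
    """Time at which walking speed first enters its terminal band.

    The band is the mean +/- max(SD, ``eps``) of the speeds over the last
    ``tail_frac`` of the trial duration.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    if duration is None:
        duration = float(t[-1])
    if duration <= 0:
        raise DataError("duration must be positive")
    tail = t >= (1.0 - tail_frac) * duration
    if not tail.any():
        raise DataError("series does not cover the trial duration")
    mean = float(np.mean(v[tail]))
    sd = max(float(np.std(v[tail], ddof=0)), eps)
    return _entry_time(t, v, mean - sd, mean + sd)


def convergence_distance(t: np.ndarray, v: np.ndarray,
                         tail_distance: float = 30.0,
                         eps: float = BAND_EPSILON) -> float:
    """Distance walked before the speed first enters its terminal band.

    The band is the mean +/- max(SD, ``eps``) of the speeds over the final
    ``tail_distance`` meters of cumulative walking distance.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    dt = np.diff(t, prepend=t[0])
    d = np.cumsum(v * dt)
    total = d[-1]
    if total < tail_distance:
        raise DataError(
            f"trial covers {total:.1f} m < tail of {tail_distance} m")
    tail = d >= total - tail_distance
    mean = float(np.mean(v[tail]))
    sd = max(float(np.std(v[tail], ddof=0)), eps)
    inside = (v >= mean - sd) & (v <= mean + sd)
    idx = np.argmax(inside)
    if not inside[idx]:
        return float(total)
    return float(d[idx])


def section_speeds(t: np.ndarray, v: np.ndarray,
                   section_length: float = 10.0, n_sections: int = 6,
                   course_length: float = 150.0,
                   starts: Optional[Sequence[float]] = None) -> np.ndarray:
    """Mean walking speed over fixed distance sections.

    By default the ``n_sections`` sections of ``section_length`` m are
    centered within equal sub-divisions of a ``course_length``-m course
    (mirroring timed 10-m sections of a 150-m walk).  Each section speed is
    distance / time across the section, with crossing times interpolated
    on the cumulative-distance curve.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    dt = np.diff(t, prepend=t[0])
    d = np.cumsum(v * dt)
    if starts is None:
        sub = course_length / n_sections
        starts = [(i + 0.5) * sub - section_length / 2.0
                  for i in range(n_sections)]
    if d[-1] < max(starts) + section_length:
        raise DataError("trial does not cover the requested sections")
    out = []
    for s in starts:
        t_in = float(np.interp(s, d, t))
        t_out = float(np.interp(s + section_length, d, t))
        out.append(section_length / (t_out - t_in))
    return np.asarray(out)


def linear_fit_corr(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Least-squares fit ``y ~ b1 x + b0`` plus Pearson R and p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise DataError("need equal-length inputs with n >= 3")
    if np.std(x) == 0:
        raise DataError("zero variance in x")
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue), float(res.pvalue))


def intra_subject_sd(speeds: pd.DataFrame, subject_col: str = "subject",
                     value_col: str = "speed") -> tuple:
    """Per-subject sample SD of repeated measurements, and their mean.

    Each subject must have at least two repeats; SD uses the n-1
    denominator.
    """
    groups = speeds.groupby(subject_col)[value_col]
    sizes = groups.size()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise DataError(f"singleton group(s): {bad}")
    sd = groups.std(ddof=1)
    return sd, float(sd.mean())


def walking_speed_series(log: TrialLog) -> tuple:
    """Per-step estimated walking speed sampled on the tick grid.

    Walking speed on a treadmill is belt speed plus the walker's lab-frame
    speed; per footstep this is ``vbar_tm + vbar_kf``, held constant
    between footsteps (zero-order hold; the pre-first-step segment holds
    the first step's value).  Returns ``(t, v_walk)`` aligned with the
    log's tick time base.
    """
    steps = log.steps
    if len(steps) == 0:
        raise DataError("log contains no steps")
    t = log.ticks["t"].to_numpy()
    v_step = (steps["vbar_tm"] + steps["vbar_kf"]).to_numpy()
    t1 = steps["t1"].to_numpy()
    idx = np.searchsorted(t1, t, side="right") - 1
    idx = np.clip(idx, 0, len(v_step) - 1)
    return t, v_step[idx]


def evaluate_tracking(log: TrialLog, accepted_only: bool = True) -> EvalReport:
    """RMS tracking errors of a trial log that carries ground truth."""
    steps = log.steps
    if "truth_vbar" not in steps.columns:
        raise DataError("log has no ground-truth step means")
    if accepted_only:
        steps = steps[steps["accepted"]]
    rms_v, rms_p = rms_step_errors(
        steps["vbar_kf"], steps["pbar_kf"],
        steps["truth_vbar"], steps["truth_pbar"])
    errs = pd.DataFrame({
        "t1": steps["t1"],
        "dv": steps["vbar_kf"] - steps["truth_vbar"],
        "dp": steps["pbar_kf"] - steps["truth_pbar"],
    })
    return EvalReport(rms_vbar=rms_v, rms_pbar=rms_p, step_errors=errs)
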