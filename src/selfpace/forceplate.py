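"""Force-plate signal conditioning and per-step gait measurements.

A dual-belt instrumented treadmill reports, per belt, the vertical ground
reaction force ``f_z``, the fore-aft ground reaction force ``f_y`` and the
fore-aft center of pressure (COP).  From these this module derives the three
measurements the state estimator consumes:

* per-sample fore-aft acceleration of the walker, ``a_mes = f_y / m``
  (Newton's second law, with ``f_y`` summed over both belts);
* per-footstep mean walking speed in the lab frame,
  ``vbar_mes = (y_f1 - y_f0) / (t1 - t0) - vbar_tm``;
* per-footstep mean position, ``pbar_mes = (y_f1 + y_f0) / 2``.

Coordinate convention (used throughout the package): lab frame, ``+y`` is
the walker's forward direction, origin at the treadmill center.  ``v_tm`` is
the magnitude of the belt-surface speed; the belt surface moves in ``-y``.
A foot resting on the belt therefore translates by ``-∫ v_tm dt``, and the
trailing foot position is the COP at the previous contact *minus* the belt
travel between the contacts.

Foot contacts are detected as rising crossings of ``f_z`` through 20% of
body weight, with a 10%-of-body-weight re-arm hysteresis to suppress
chatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

GRAVITY = 9.81  # m/s^2

#: fraction of body weight a belt's f_z must exceed for a foot contact
CONTACT_THRESHOLD_FRAC = 0.2
#: fraction of body weight f_z must fall below before a belt re-arms
REARM_FRAC = 0.1
#: fraction of body weight below which the COP ratio is considered invalid
COP_FLOOR_FRAC = 0.05

#: longest plausible step; longer inter-contact intervals are rejected
MAX_STEP_TIME = 1.2  # s
#: shortest plausible step (re-trigger guard)
MIN_STEP_TIME = 0.2  # s

CSV_COLUMNS = ["t", "fz_l", "fy_l", "copy_l", "fz_r", "fy_r", "copy_r", "vtm"]

BELTS = ("left", "right")


class ConfigurationError(ValueError):
    """Invalid or missing configuration (mass, cutoff, thresholds...)."""


class DataError(ValueError):
    """Malformed or incomplete input data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ForcePlateSeries:
    """Uniformly sampled dual-belt force-plate record.

    All channels share one time base at rate ``fs`` (samples per second);
    sample ``k`` is at ``t = k / fs``.  ``copy_*`` is NaN where the belt is
    unloaded (COP undefined).  ``vtm`` is the belt-speed magnitude history.
    """

    fs: float
    fz_l: np.ndarray
    fy_l: np.ndarray
    copy_l: np.ndarray
    fz_r: np.ndarray
    fy_r: np.ndarray
    copy_r: np.ndarray
    vtm: np.ndarray
    body_mass: Optional[float] = None
    body_weight: Optional[float] = None

    def __post_init__(self) -> None:
        arrays = [self.fz_l, self.fy_l, self.copy_l,
                  self.fz_r, self.fy_r, self.copy_r, self.vtm]
        n = len(arrays[0])
        for a in arrays:
            if len(a) != n:
                raise DataError("all channels must have equal length")
        for name in ("fz_l", "fy_l", "fz_r", "fy_r", "vtm"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise DataError(f"non-finite samples in channel {name!r}")
        if np.any(self.vtm < 0):
            raise DataError("belt speed must be non-negative")
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return len(self.vtm)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def fz(self, belt: str) -> np.ndarray:
        return self.fz_l if belt == "left" else self.fz_r

    def copy(self, belt: str) -> np.ndarray:
        return self.copy_l if belt == "left" else self.copy_r

    @property
    def fy_total(self) -> np.ndarray:
        return self.fy_l + self.fy_r

    @property
    def fz_total(self) -> np.ndarray:
        return self.fz_l + self.fz_r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "fz_l": self.fz_l, "fy_l": self.fy_l, "copy_l": self.copy_l,
            "fz_r": self.fz_r, "fy_r": self.fy_r, "copy_r": self.copy_r,
            "vtm": self.vtm,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, body_mass: Optional[float] = None,
                   body_weight: Optional[float] = None) -> "ForcePlateSeries":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"missing columns: {missing}")
        if len(df) < 2:
            raise DataError("need at least two samples")
        t = df["t"].to_numpy(float)
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise DataError("time column is not uniformly sampled")
        fs = 1.0 / dt[0]
        if body_mass is not None and body_weight is None:
            body_weight = body_mass * GRAVITY
        return cls(
            fs=fs,
            fz_l=df["fz_l"].to_numpy(float), fy_l=df["fy_l"].to_numpy(float),
            copy_l=df["copy_l"].to_numpy(float),
            fz_r=df["fz_r"].to_numpy(float), fy_r=df["fy_r"].to_numpy(float),
            copy_r=df["copy_r"].to_numpy(float),
            vtm=df["vtm"].to_numpy(float),
            body_mass=body_mass, body_weight=body_weight,
        )


@dataclass(frozen=True)
class ContactEvent:
    """A rising foot-contact detection on one belt."""

    t_contact: float
    belt: str
    cop_at_contact: float
    sample_index: int


@dataclass(frozen=True)
class StepMeasurement:
    """One footstep between consecutive contact detections.

    ``y_f1`` is the leading-foot COP at the new contact; ``y_f0`` is the
    trailing foot's lab-frame position at the same instant (previous contact
    COP carried backwards with the belt).  ``vbar_mes`` and ``pbar_mes`` are
    the step-mean walking speed and position measurements; ``vbar_tm`` is
    the mean belt speed over the step.
    """

    t0: float
    t1: float
    y_f0: float
    y_f1: float
    vbar_mes: float
    pbar_mes: float
    vbar_tm: float
    accepted: bool
    belt: str = ""

    @property
    def step_time(self) -> float:
        return self.t1 - self.t0


# ---------------------------------------------------------------------------
# signal conditioning
# ---------------------------------------------------------------------------


def butter_coefficients(order: int, fc: float, fs: float):
    """Low-pass Butterworth (b, a) with cutoff ``fc`` Hz at rate ``fs``."""
    if order < 1:
        raise ConfigurationError("filter order must be >= 1")
    if not 0 < fc < fs / 2:
        raise ConfigurationError(
            f"cutoff {fc} Hz must lie in (0, Nyquist={fs / 2} Hz)")
    return signal.butter(order, fc, btype="low", fs=fs)


class CausalLowpass:
    """Streaming (sample-by-sample) IIR low-pass, direct form II transposed.

    State is initialized to the filter's steady-state response to the first
    sample, so a constant input passes through with no startup transient.
    The recursion is identical to :func:`scipy.signal.lfilter`.
    """

    def __init__(self, b: np.ndarray, a: np.ndarray):
        self.b = [float(x) for x in b]
        self.a = [float(x) for x in a]
        self._zi_unit = signal.lfilter_zi(b, a)
        self.z: Optional[list] = None

    def update(self, x: float) -> float:
        b, a = self.b, self.a
        if self.z is None:
            self.z = [float(v) for v in self._zi_unit * x]
        z = self.z
        y = b[0] * x + z[0]
        n = len(z)
        for i in range(n - 1):
            z[i] = b[i + 1] * x - a[i + 1] * y + z[i + 1]
        z[n - 1] = b[n] * x - a[n] * y
        return y


def _lfilter_init(b, a, x: np.ndarray) -> np.ndarray:
    zi = signal.lfilter_zi(b, a) * x[0]
    y, _ = signal.lfilter(b, a, x, zi=zi)
    return y


def lowpass(series: ForcePlateSeries, order: int = 3,
            fc: float = 25.0) -> ForcePlateSeries:
    """Causally low-pass every force channel; recompute COP from the ratio.

    Force and fore-aft moment proxy (``f_z * cop_y``) channels are filtered
    and the COP is re-formed as their ratio, which is well-behaved because
    the ratio is only evaluated where the filtered ``f_z`` exceeds the COP
    validity floor (5% of body weight).  Filtering the COP ratio directly
    would be ill-behaved near an unloaded belt.  The belt-speed history is
    passed through untouched.
    """
    if series.body_weight is None:
        raise ConfigurationError(
            "body_weight must be set (see calibrate_body_weight) before "
            "filtering, to define the COP validity floor")
    b, a = butter_coefficients(order, fc, series.fs)
    floor = COP_FLOOR_FRAC * series.body_weight
    out = {}
    for side in ("l", "r"):
        fz = getattr(series, f"fz_{side}")
        fy = getattr(series, f"fy_{side}")
        cop = getattr(series, f"copy_{side}")
        mom = fz * np.nan_to_num(cop)
        fz_f = _lfilter_init(b, a, fz)
        fy_f = _lfilter_init(b, a, fy)
        mom_f = _lfilter_init(b, a, mom)
        with np.errstate(divide="ignore", invalid="ignore"):
            cop_f = np.where(fz_f >= floor, mom_f / fz_f, np.nan)
        out[f"fz_{side}"] = fz_f
        out[f"fy_{side}"] = fy_f
        out[f"copy_{side}"] = cop_f
    return replace(series, **out)


def compute_cop(fz: np.ndarray, moment: np.ndarray, origin: float = 0.0,
                floor: float = 35.0) -> np.ndarray:
    """Fore-aft COP from a plate's vertical force and fore-aft moment term.

    ``cop_y = moment / fz + origin`` where ``fz >= floor`` (N); NaN
    (invalid) elsewhere, never silently zero.
    """
    fz = np.asarray(fz, float)
    moment = np.asarray(moment, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cop = np.where(fz >= floor, moment / fz + origin, np.nan)
    return cop


def calibrate_body_weight(series: ForcePlateSeries,
                          window: Optional[tuple] = None,
                          min_duration: float = 2.0) -> tuple:
    """Body weight (N) and mass (kg) from a quiet-standing window.

    ``window`` is a ``(t_start, t_stop)`` pair in seconds; default is the
    whole record.  Weight is the mean total vertical force over the window;
    mass is weight / g.
    """
    t = series.t
    if window is None:
        mask = np.ones(series.n, bool)
    else:
        mask = (t >= window[0]) & (t < window[1])
    if mask.sum() < min_duration * series.fs:
        raise DataError(
            f"calibration window shorter than {min_duration} s")
    bw = float(np.mean(series.fz_total[mask]))
    return bw, bw / GRAVITY


# ---------------------------------------------------------------------------
# contact detection
# ---------------------------------------------------------------------------


class ContactDetector:
    """Streaming rising-edge contact detector with hysteresis.

    A belt fires when its (already conditioned) ``f_z`` crosses
    ``threshold_frac * body_weight`` upward while armed; it disarms on
    firing and re-arms only after ``f_z`` falls below
    ``rearm_frac * body_weight``.  If both belts cross within the same
    sample the belt with the larger ``f_z`` wins and the other is
    suppressed until it re-arms.  A belt already above threshold at the
    first sample is treated as mid-stance (no event).
    """

    def __init__(self, body_weight: float,
                 threshold_frac: float = CONTACT_THRESHOLD_FRAC,
                 rearm_frac: float = REARM_FRAC):
        if body_weight is None or body_weight <= 0:
            raise ConfigurationError("body_weight must be set and positive")
        self.thr = threshold_frac * body_weight
        self.lo = rearm_frac * body_weight
        self.armed = {"left": None, "right": None}  # None until first sample

    def update(self, fz_l: float, fz_r: float) -> Optional[str]:
        """Process one sample pair; return the firing belt or None."""
        fz = {"left": fz_l, "right": fz_r}
        crossing = []
        for belt in BELTS:
            x = fz[belt]
            if self.armed[belt] is None:
                self.armed[belt] = x <= self.thr
                continue
            if self.armed[belt]:
                if x > self.thr:
                    crossing.append(belt)
            elif x < self.lo:
                self.armed[belt] = True
        if not crossing:
            return None
        if len(crossing) == 2:
            winner = "left" if fz_l >= fz_r else "right"
        else:
            winner = crossing[0]
        for belt in crossing:
            self.armed[belt] = False
        return winner


def detect_contacts(series: ForcePlateSeries,
                    threshold_frac: float = CONTACT_THRESHOLD_FRAC,
                    rearm_frac: float = REARM_FRAC) -> list:
    """Foot-contact events from a conditioned series (see :func:`lowpass`).

    Each event carries the firing belt's COP at the crossing sample.
    """
    det = ContactDetector(series.body_weight, threshold_frac, rearm_frac)
    events = []
    fz_l, fz_r = series.fz_l, series.fz_r
    cop = {"left": series.copy_l, "right": series.copy_r}
    for k in range(series.n):
        belt = det.update(fz_l[k], fz_r[k])
        if belt is not None:
            events.append(ContactEvent(
                t_contact=k / series.fs, belt=belt,
                cop_at_contact=float(cop[belt][k]), sample_index=k))
    return events


# ---------------------------------------------------------------------------
# per-step measurements
# ---------------------------------------------------------------------------


def belt_travel(vtm: np.ndarray, fs: float, i0: int, i1: int) -> float:
    """Belt-surface travel (m) between samples ``i0`` and ``i1``.

    Rectangle rule at the sampling rate: ``sum(vtm[i0+1 : i1+1]) / fs``.
    The same discretization defines the per-step mean belt speed, so the
    step-speed identity holds exactly.
    """
    if i1 >= len(vtm):
        raise DataError("belt-speed history does not cover the step")
    return float(np.sum(vtm[i0 + 1:i1 + 1])) / fs


def foot_positions(prev: ContactEvent, curr: ContactEvent,
                   vtm: np.ndarray, fs: float) -> tuple:
    """Lab-frame trailing and leading foot positions ``(y_f0, y_f1)``.

    ``y_f1`` is the new contact's COP.  ``y_f0`` is the previous contact's
    COP translated with the belt surface over the step: the belt moves in
    ``-y``, so ``y_f0 = prev_cop - ∫ v_tm dt``.
    """
    if not prev.t_contact < curr.t_contact:
        raise DataError("contacts out of order")
    travel = belt_travel(vtm, fs, prev.sample_index, curr.sample_index)
    return prev.cop_at_contact - travel, curr.cop_at_contact


def step_measurement(prev: ContactEvent, curr: ContactEvent,
                     vtm: np.ndarray, fs: float,
                     max_step: float = MAX_STEP_TIME,
                     min_step: float = MIN_STEP_TIME) -> StepMeasurement:
    """Step-mean walking speed and position from two consecutive contacts.

    ``vbar_mes = (y_f1 - y_f0)/(t1 - t0) - vbar_tm`` (step length over step
    time minus mean belt speed) and ``pbar_mes = (y_f1 + y_f0)/2`` (midpoint
    of the two foot placements).  Steps longer than ``max_step`` (belt
    crossovers) or shorter than ``min_step`` (re-triggers) are flagged
    rejected.
    """
    y_f0, y_f1 = foot_positions(prev, curr, vtm, fs)
    dt = (curr.sample_index - prev.sample_index) / fs
    travel = belt_travel(vtm, fs, prev.sample_index, curr.sample_index)
    vbar_tm = travel / dt
    vbar_mes = (y_f1 - y_f0) / dt - vbar_tm
    pbar_mes = 0.5 * (y_f1 + y_f0)
    accepted = (min_step <= dt <= max_step) and np.isfinite(vbar_mes + pbar_mes)
    return StepMeasurement(
        t0=prev.t_contact, t1=curr.t_contact, y_f0=y_f0, y_f1=y_f1,
        vbar_mes=vbar_mes, pbar_mes=pbar_mes, vbar_tm=vbar_tm,
        accepted=bool(accepted), belt=curr.belt)


def accel_measurement(fy_total: np.ndarray, mass: float) -> np.ndarray:
    """Fore-aft walker acceleration ``a_mes = f_y / m`` (Newton's 2nd law)."""
    if mass is None or mass <= 0:
        raise ConfigurationError("body mass must be set and positive")
    return np.asarray(fy_total, float) / mass


def events_frame(events: list, steps: list) -> pd.DataFrame:
    """Tabulate contact events with their step measurements for CSV export."""
    rows = []
    for i, ev in enumerate(events):
        row = {"t_contact": ev.t_contact, "belt": ev.belt,
               "cop_y": ev.cop_at_contact,
               "step_time": np.nan, "yf0": np.nan, "yf1": np.nan,
               "vmes": np.nan, "pmes": np.nan, "accepted": False}
        if i >= 1 and i - 1 < len(steps):
            s = steps[i - 1]
            row.update(step_time=s.step_time, yf0=s.y_f0, yf1=s.y_f1,
                       vmes=s.vbar_mes, pmes=s.pbar_mes, accepted=s.accepted)
        rows.append(row)
    return pd.DataFrame(rows)
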