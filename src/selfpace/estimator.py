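"""Kalman filter tracking a treadmill walker's lab-frame speed and position.

The filter state is ``x = [p, v]`` (fore-aft position and velocity in the
lab frame).  Every sample (1 kHz) the state is *predicted* from the measured
fore-aft acceleration ``a_mes = f_y / m``:

    x <- A x + B a_mes,      P <- A P A' + sigma_a^2 B B'

with ``A = [[1, dt], [0, 1]]`` and ``B = [dt^2/2, dt]``.  Once per footstep,
when a new foot contact is detected, the state is *corrected* with the
step-mean position and speed measurements (observation matrix = identity):

    K = P (P + R)^-1
    x <- x + K ([pbar_mes, vbar_mes] - [pbar_KF, vbar_KF])
    P <- (I - K) P

where ``pbar_KF, vbar_KF`` are the running means of the predicted state
since the previous contact.  Steps of implausible duration (> 1.2 s, belt
crossovers; or < the minimum duration, re-triggers) skip the correction.

The noise constants (process noise sigma_a^2 = 2.9 (m/s^2)^2, measurement
covariance R = 1e-3 diag(0.6, 7.2), initial covariance P0) are empirical
values for human treadmill walking at 0.8-1.8 m/s, obtained by comparing
force-plate measurements against motion capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import forceplate as fp
from .forceplate import (CausalLowpass, ConfigurationError, ContactDetector,
                         ContactEvent, DataError, ForcePlateSeries,
                         StepMeasurement, butter_coefficients)
from .trial import TrialLog


@dataclass(frozen=True)
class FilterParams:
    """Kalman filter constants (defaults as used on the real system)."""

    dt: float = 1e-3                 # s, sample period (1 kHz)
    sigma_a2: float = 2.9            # (m/s^2)^2 process (acceleration) noise
    r_p: float = 0.6e-3              # m^2, step-position measurement variance
    r_v: float = 7.2e-3              # (m/s)^2, step-speed measurement variance
    p0_00: float = 3.5e-3            # initial error covariance P0
    p0_01: float = 1.5e-3
    p0_11: float = 1.6e-3
    max_step: float = fp.MAX_STEP_TIME   # s, crossover rejection limit
    min_step: float = fp.MIN_STEP_TIME   # s, re-trigger guard

    @property
    def A(self) -> np.ndarray:
        return np.array([[1.0, self.dt], [0.0, 1.0]])

    @property
    def B(self) -> np.ndarray:
        return np.array([0.5 * self.dt ** 2, self.dt])

    @property
    def Q_add(self) -> np.ndarray:
        """Additive process-noise term ``sigma_a^2 * B B'`` per time update."""
        B = self.B
        return self.sigma_a2 * np.outer(B, B)

    @property
    def R(self) -> np.ndarray:
        return np.diag([self.r_p, self.r_v])

    @property
    def P0(self) -> np.ndarray:
        return np.array([[self.p0_00, self.p0_01],
                         [self.p0_01, self.p0_11]])


@dataclass
class FilterState:
    """Instantaneous filter state plus per-step running-mean accumulators."""

    p_kf: float = 0.0
    v_kf: float = 0.0
    p00: float = 0.0
    p01: float = 0.0
    p11: float = 0.0
    sum_p: float = 0.0
    sum_v: float = 0.0
    n_acc: int = 0
    last_event: Optional[ContactEvent] = None

    @property
    def P(self) -> np.ndarray:
        return np.array([[self.p00, self.p01], [self.p01, self.p11]])

    @property
    def pbar_kf(self) -> float:
        """Mean estimated position since the last contact."""
        return self.sum_p / self.n_acc

    @property
    def vbar_kf(self) -> float:
        """Mean estimated speed since the last contact."""
        return self.sum_v / self.n_acc

    def reset_accumulators(self) -> None:
        self.sum_p = 0.0
        self.sum_v = 0.0
        self.n_acc = 0


def init(params: FilterParams) -> FilterState:
    """Initial state: ``p = v = 0``, ``P = P0``, empty accumulators."""
    return FilterState(p00=params.p0_00, p01=params.p0_01, p11=params.p0_11)


def time_update(state: FilterState, a_mes: float,
                params: FilterParams) -> FilterState:
    """Predict one sample ahead from measured acceleration (in place)."""
    if not np.isfinite(a_mes):
        raise DataError("non-finite acceleration measurement")
    dt = params.dt
    state.p_kf += state.v_kf * dt + 0.5 * a_mes * dt * dt
    state.v_kf += a_mes * dt
    # P <- A P A' + sigma_a^2 B B'
    p00, p01, p11 = state.p00, state.p01, state.p11
    s = params.sigma_a2
    state.p00 = p00 + dt * (2.0 * p01 + dt * p11) + s * 0.25 * dt ** 4
    state.p01 = p01 + dt * p11 + s * 0.5 * dt ** 3
    state.p11 = p11 + s * dt * dt
    state.sum_p += state.p_kf
    state.sum_v += state.v_kf
    state.n_acc += 1
    return state


def measurement_update(state: FilterState, meas: StepMeasurement,
                       params: FilterParams) -> FilterState:
    """Correct the state with a step measurement (in place).

    The innovation compares the measured step means against the running
    means of the predicted state; the correction is applied to the
    instantaneous state.  The covariance update ``(I - K) P`` is
    symmetrized afterwards.
    """
    if not meas.accepted:
        raise ValueError("measurement_update requires an accepted step")
    if state.n_acc == 0:
        raise ValueError("no predicted samples accumulated since last contact")
    p00, p01, p11 = state.p00, state.p01, state.p11
    s00 = p00 + params.r_p
    s11 = p11 + params.r_v
    det = s00 * s11 - p01 * p01
    assert det > 0, "P + R must be positive definite"
    k00 = (p00 * s11 - p01 * p01) / det
    k01 = (p01 * s00 - p00 * p01) / det
    k10 = (p01 * s11 - p11 * p01) / det
    k11 = (p11 * s00 - p01 * p01) / det
    ip = meas.pbar_mes - state.pbar_kf
    iv = meas.vbar_mes - state.vbar_kf
    state.p_kf += k00 * ip + k01 * iv
    state.v_kf += k10 * ip + k11 * iv
    m00, m01, m10, m11 = 1.0 - k00, -k01, -k10, 1.0 - k11
    q00 = m00 * p00 + m01 * p01
    q01 = m00 * p01 + m01 * p11
    q10 = m10 * p00 + m11 * p01
    q11 = m10 * p01 + m11 * p11
    state.p00 = q00
    state.p01 = 0.5 * (q01 + q10)
    state.p11 = q11
    return state


def handle_contact(state: FilterState, meas: Optional[StepMeasurement],
                   params: FilterParams) -> bool:
    """Process a detected contact; return whether a correction was applied.

    Accepted steps trigger the measurement update.  Rejected steps (and the
    first contact of a trial, which yields no step) skip it.  Either way the
    accumulators reset and the contact becomes the reference for the next
    step.
    """
    applied = False
    if meas is not None and meas.accepted and state.n_acc > 0:
        measurement_update(state, meas, params)
        applied = True
    state.reset_accumulators()
    return applied


def dead_reckoning(a_mes: np.ndarray, params: FilterParams,
                   p0: float = 0.0, v0: float = 0.0) -> tuple:
    """Time updates only (no step corrections), vectorized.

    Returns ``(p, v)`` arrays, sample ``k`` holding the state after
    processing ``a_mes[k]`` -- identical to looping :func:`time_update`.
    Used to demonstrate how force integration alone diverges.
    """
    a = np.asarray(a_mes, float)
    dt = params.dt
    v = v0 + dt * np.cumsum(a)
    v_before = np.concatenate(([v0], v[:-1]))
    p = p0 + np.cumsum(v_before * dt + 0.5 * a * dt * dt)
    return p, v


@dataclass(frozen=True)
class StepResult:
    """What one detected contact produced, for control and logging."""

    event: ContactEvent
    meas: Optional[StepMeasurement]   # None at the first contact of a trial
    applied: bool                     # measurement update performed
    pbar_kf: float                    # step-mean estimates fed to the controller
    vbar_kf: float


class OnlineEstimator:
    """Streaming pipeline: conditioning, contact detection, Kalman filter.

    Feed raw force-plate samples one at a time through :meth:`tick`; the
    pipeline low-pass filters the force and COP-moment channels causally,
    detects foot contacts on the filtered vertical force, forms step
    measurements, and runs the filter's time and measurement updates.  The
    offline replay (:func:`run_offline`) and the closed-loop simulator both
    drive this same loop, so offline and online results are identical by
    construction.
    """

    def __init__(self, params: FilterParams, body_mass: float,
                 body_weight: float, fs: float,
                 lowpass_order: int = 3, lowpass_fc: float = 25.0,
                 measurement_updates: bool = True):
        if body_mass is None or body_mass <= 0:
            raise ConfigurationError("body mass must be set and positive")
        if body_weight is None or body_weight <= 0:
            raise ConfigurationError("body weight must be set and positive")
        if abs(fs * params.dt - 1.0) > 1e-9:
            raise ConfigurationError(
                f"sample rate {fs} Hz inconsistent with filter dt={params.dt}")
        self.params = params
        self.mass = body_mass
        self.body_weight = body_weight
        self.fs = fs
        self.cop_floor = fp.COP_FLOOR_FRAC * body_weight
        self.measurement_updates = measurement_updates
        b, a = butter_coefficients(lowpass_order, lowpass_fc, fs)
        self._filters = [CausalLowpass(b, a) for _ in range(6)]
        self.detector = ContactDetector(body_weight)
        self.state = init(params)
        self.k = -1               # current sample index
        self._travel = 0.0        # cumulative belt travel sum(vtm)/fs
        self._travel_at_prev = 0.0
        self.n_rejected = 0

    def tick(self, fz_l: float, fy_l: float, copy_l: float,
             fz_r: float, fy_r: float, copy_r: float,
             vtm: float) -> tuple:
        """Process one raw sample; returns ``(filtered, step_result)``.

        ``filtered`` is ``(fz_l, fy_l, cop_l, fz_r, fy_r, cop_r, a_mes)``
        after conditioning; ``step_result`` is a :class:`StepResult` when a
        contact was detected at this sample, else None.
        """
        self.k += 1
        if self.k > 0:
            self._travel += vtm / self.fs
        flt = self._filters
        fzl = flt[0].update(fz_l)
        fyl = flt[1].update(fy_l)
        moml = flt[2].update(fz_l * (copy_l if copy_l == copy_l else 0.0))
        fzr = flt[3].update(fz_r)
        fyr = flt[4].update(fy_r)
        momr = flt[5].update(fz_r * (copy_r if copy_r == copy_r else 0.0))
        copl = moml / fzl if fzl >= self.cop_floor else float("nan")
        copr = momr / fzr if fzr >= self.cop_floor else float("nan")
        a_mes = (fyl + fyr) / self.mass

        time_update(self.state, a_mes, self.params)

        result = None
        belt = self.detector.update(fzl, fzr)
        if belt is not None:
            cop = copl if belt == "left" else copr
            event = ContactEvent(t_contact=self.k / self.fs, belt=belt,
                                 cop_at_contact=cop, sample_index=self.k)
            result = self._on_contact(event)
        return (fzl, fyl, copl, fzr, fyr, copr, a_mes), result

    def _on_contact(self, event: ContactEvent) -> StepResult:
        st = self.state
        prev = st.last_event
        meas = None
        if prev is not None:
            dt = (event.sample_index - prev.sample_index) / self.fs
            travel = self._travel - self._travel_at_prev
            y_f0 = prev.cop_at_contact - travel
            y_f1 = event.cop_at_contact
            vbar_tm = travel / dt
            vbar_mes = (y_f1 - y_f0) / dt - vbar_tm
            pbar_mes = 0.5 * (y_f1 + y_f0)
            accepted = (self.params.min_step <= dt <= self.params.max_step
                        and np.isfinite(vbar_mes + pbar_mes))
            meas = StepMeasurement(
                t0=prev.t_contact, t1=event.t_contact, y_f0=y_f0, y_f1=y_f1,
                vbar_mes=vbar_mes, pbar_mes=pbar_mes, vbar_tm=vbar_tm,
                accepted=bool(accepted), belt=event.belt)
            if not accepted:
                self.n_rejected += 1
        pbar_kf = st.pbar_kf if st.n_acc > 0 else st.p_kf
        vbar_kf = st.vbar_kf if st.n_acc > 0 else st.v_kf
        if self.measurement_updates:
            applied = handle_contact(st, meas, self.params)
        else:
            applied = False
            st.reset_accumulators()
        st.last_event = event
        self._travel_at_prev = self._travel
        return StepResult(event=event, meas=meas, applied=applied,
                          pbar_kf=pbar_kf, vbar_kf=vbar_kf)


def _steps_frame(results: list) -> pd.DataFrame:
    rows = []
    for r in results:
        if r.meas is None:
            continue
        m = r.meas
        rows.append({
            "t0": m.t0, "t1": m.t1, "belt": m.belt,
            "yf0": m.y_f0, "yf1": m.y_f1,
            "vbar_mes": m.vbar_mes, "pbar_mes": m.pbar_mes,
            "vbar_tm": m.vbar_tm, "accepted": m.accepted,
            "applied": r.applied,
            "pbar_kf": r.pbar_kf, "vbar_kf": r.vbar_kf,
        })
    columns = ["t0", "t1", "belt", "yf0", "yf1", "vbar_mes", "pbar_mes",
               "vbar_tm", "accepted", "applied", "pbar_kf", "vbar_kf"]
    return pd.DataFrame(rows, columns=columns)


def _truth_step_means(steps: pd.DataFrame, truth: pd.DataFrame,
                      fs: float) -> pd.DataFrame:
    """Ground-truth step means over each detected step's sample window.

    The window matches the filter's accumulators: samples ``i0+1 .. i1``
    for a step between contacts at samples ``i0`` and ``i1``.
    """
    tp = truth["truth_p"].to_numpy()
    tv = truth["truth_v"].to_numpy()
    vbar, pbar = [], []
    for _, row in steps.iterrows():
        i0 = int(round(row["t0"] * fs))
        i1 = int(round(row["t1"] * fs))
        sl = slice(i0 + 1, i1 + 1)
        pbar.append(float(np.mean(tp[sl])))
        vbar.append(float(np.mean(tv[sl])))
    out = steps.copy()
    out["truth_pbar"] = pbar
    out["truth_vbar"] = vbar
    return out


def run_offline(series: ForcePlateSeries, params: FilterParams,
                lowpass_order: int = 3, lowpass_fc: float = 25.0,
                measurement_updates: bool = True,
                truth: Optional[pd.DataFrame] = None) -> TrialLog:
    """Replay a recorded (or synthesized) raw series through the pipeline.

    Returns a :class:`TrialLog` whose ``ticks`` carry the estimates and
    covariance diagonal/off-diagonal, and whose ``steps`` carry the step
    measurements, step-mean estimates and acceptance/application flags.
    If ``truth`` (a frame with ``truth_p``/``truth_v`` per tick) is given,
    ground-truth step means over the detected step windows are appended.
    """
    est = OnlineEstimator(params, series.body_mass, series.body_weight,
                          series.fs, lowpass_order, lowpass_fc,
                          measurement_updates)
    n = series.n
    p_kf = np.empty(n)
    v_kf = np.empty(n)
    P00 = np.empty(n)
    P01 = np.empty(n)
    P11 = np.empty(n)
    results = []
    fz_l, fy_l, copy_l = series.fz_l, series.fy_l, series.copy_l
    fz_r, fy_r, copy_r = series.fz_r, series.fy_r, series.copy_r
    vtm = series.vtm
    st = est.state
    for k in range(n):
        _, res = est.tick(fz_l[k], fy_l[k], copy_l[k],
                          fz_r[k], fy_r[k], copy_r[k], vtm[k])
        if res is not None:
            results.append(res)
        p_kf[k] = st.p_kf
        v_kf[k] = st.v_kf
        P00[k] = st.p00
        P01[k] = st.p01
        P11[k] = st.p11
    ticks = pd.DataFrame({
        "t": series.t, "vtm": vtm,
        "p_kf": p_kf, "v_kf": v_kf, "P00": P00, "P01": P01, "P11": P11,
    })
    steps = _steps_frame(results)
    if truth is not None:
        ticks["truth_p"] = truth["truth_p"].to_numpy()
        ticks["truth_v"] = truth["truth_v"].to_numpy()
        if len(steps):
            steps = _truth_step_means(steps, truth, series.fs)
    meta = {
        "kind": "estimate",
        "body_mass": series.body_mass,
        "body_weight": series.body_weight,
        "fs": series.fs,
        "n_rejected": est.n_rejected,
        "measurement_updates": measurement_updates,
    }
    return TrialLog(ticks=ticks, steps=steps, meta=meta)
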