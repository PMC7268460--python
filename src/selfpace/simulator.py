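"""Virtual walker and treadmill: Newton-consistent dual-belt gait synthesis.

The simulator stands in for the human subject and the instrumented
treadmill so the estimate->control loop can be exercised end to end.  It is
deliberately minimal; its load-bearing property is *physical consistency*
with the measurement model the estimator assumes, not biomechanical
realism:

* the total fore-aft force equals mass times the center-of-mass (COM)
  lab-frame acceleration at every sample, by construction, so integrating
  it reproduces the COM trajectory exactly;
* vertical load sums to body weight and transfers between belts over the
  double-support window with a raised-cosine profile (vertical COM dynamics
  are not modeled -- the estimator only uses ``f_z`` for contact timing);
* each foot's COP is a point at the foot's lab position, riding backward
  with the belt during stance.

The walker advances its COM with a mean drift plus a within-step sinusoidal
speed oscillation, steering its belt-relative speed toward a preferred
speed (or toward the belt speed, for scripted fixed-speed trials) with a
weak station-keeping correction, which stands in for how people hold
station on a treadmill.  Footsteps alternate belts, placed symmetrically
about the COM with length = belt-relative speed x step time, where step
time follows a linear cadence law ``T = c0 - c1 w``.

Sensor noise is injected at the sensor level so the estimator's noise
matrices keep their meaning: white acceleration-equivalent noise on the
fore-aft force channels, a per-stance offset on each foot's COP reading,
and jitter on step timing.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import controller as ctl
from . import estimator as est
from .forceplate import GRAVITY, ConfigurationError, ForcePlateSeries
from .trial import TrialLog

PROFILE_NAMES = ("const_0.8", "const_1.3", "const_1.8",
                 "staircase_up", "staircase_down")

#: plateau sequence of the scripted staircase trials (m/s, 10 s each)
STAIRCASE_SPEEDS = (0.8, 1.0, 1.2, 1.4, 1.6, 1.8)
STAIRCASE_PLATEAU = 10.0  # s


@dataclass(frozen=True)
class WalkerParams:
    """Virtual-walker morphology, gait law, behavior and sensor noise."""

    mass: float = 70.0              # kg
    v_pref: float = 1.3             # m/s preferred belt-relative speed
    c0: float = 0.8                 # s, cadence law T_step = c0 - c1*w
    c1: float = 0.2                 # s^2/m
    t_step_min: float = 0.3         # s, cadence law floor
    t_step_max: float = 1.5         # s
    double_support_frac: float = 0.2   # of step time
    osc_amp: float = 0.15           # m/s within-step speed oscillation
    k_station: float = 0.1          # 1/s station-keeping gain
    station: float = 0.0            # m, station point
    y0: Optional[float] = None      # m, initial COM position (default station)
    accel_noise_std: float = 1.7    # m/s^2 white accel-equivalent force noise
    cop_noise_std: float = 0.024    # m, per-stance COP reading offset
    step_time_jitter_std: float = 0.02  # s
    crossover_prob: float = 0.0     # per-step probability of a belt crossover
    crossover_steps: tuple = ()     # step indices forced to cross over

    def __post_init__(self):
        if self.mass <= 0:
            raise ConfigurationError("mass must be positive")
        if not 0 < self.double_support_frac < 1:
            raise ConfigurationError("double-support fraction must be in (0,1)")
        if self.t_step_min < 0.3 - 1e-12 or self.t_step_max > 1.5 + 1e-12:
            raise ConfigurationError("step-time bounds must stay in [0.3, 1.5] s")

    @property
    def body_weight(self) -> float:
        return self.mass * GRAVITY


def inject_crossover(walker: WalkerParams, step_index: int) -> WalkerParams:
    """Force the given footstep onto its predecessor's belt.

    The merged stance produces no threshold crossing on the contralateral
    plate, so the detector sees one long inter-contact interval -- the
    signature of a real belt-crossover step.
    """
    return replace(walker,
                   crossover_steps=tuple(walker.crossover_steps) + (int(step_index),))


@dataclass
class TreadmillModel:
    """Belt executing speed commands: ramp at the commanded acceleration.

    The belt speed is continuous, moves toward the active command's target
    at its |a_tgt| and holds on arrival; it never goes negative.
    """

    v: float
    cmd: Optional[ctl.TreadmillCommand] = None

    def apply(self, cmd: ctl.TreadmillCommand) -> None:
        self.cmd = cmd

    def tick(self, dt: float) -> float:
        c = self.cmd
        if c is not None:
            dv = c.v_tgt - self.v
            step = abs(c.a_tgt) * dt
            if abs(dv) <= step:
                self.v = c.v_tgt
            else:
                self.v += math.copysign(step, dv)
        if self.v < 0.0:
            self.v = 0.0
        return self.v


def scripted_profiles(name: str, duration: float = 60.0,
                      fs: float = 1000.0) -> np.ndarray:
    """Belt-speed schedule for the scripted evaluation trials.

    ``const_*`` hold one speed; ``staircase_up`` changes every 10 s through
    0.8, 1.0, 1.2, 1.4, 1.6, 1.8 m/s and ``staircase_down`` presents the
    same speeds in reverse order.
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if name.startswith("const_"):
        try:
            v = float(name.split("_", 1)[1])
        except ValueError:
            raise ConfigurationError(f"unknown profile {name!r}") from None
        return np.full(n, v)
    if name == "staircase_up":
        speeds = STAIRCASE_SPEEDS
    elif name == "staircase_down":
        speeds = STAIRCASE_SPEEDS[::-1]
    else:
        raise ConfigurationError(
            f"unknown profile {name!r}; expected one of {PROFILE_NAMES}")
    idx = np.minimum((t // STAIRCASE_PLATEAU).astype(int), len(speeds) - 1)
    return np.asarray(speeds, float)[idx]


@dataclass
class _Foot:
    belt: str
    pos: float        # true lab position
    cop_off: float    # COP reading offset (sensor noise)


class _WalkerSim:
    """Tick-level walker advancing COM dynamics and footstep placement."""

    def __init__(self, params: WalkerParams, fs: float, n_ticks: int,
                 rng: np.random.Generator, follow_belt: bool = False):
        self.p = params
        self.fs = fs
        self.dt = 1.0 / fs
        self.rng = rng
        self.follow_belt = follow_belt
        self.mg = params.body_weight
        self.y = params.station if params.y0 is None else params.y0
        self.v = 0.0
        self.k = -1
        self.step_idx = -1
        self.t_last = 0.0
        self.T_cur = 0.0
        self.T_ds = 0.0
        self.next_contact = None
        self.cur: Optional[_Foot] = None
        self.prev: Optional[_Foot] = None
        self.truth_steps: list = []
        if params.accel_noise_std > 0:
            self._a_noise = rng.normal(0.0, params.accel_noise_std, n_ticks)
        else:
            self._a_noise = np.zeros(n_ticks)

    def _cop_off(self) -> float:
        s = self.p.cop_noise_std
        return float(self.rng.normal(0.0, s)) if s > 0 else 0.0

    def _draw_T(self, w: float) -> float:
        p = self.p
        T = p.c0 - p.c1 * w
        if p.step_time_jitter_std > 0:
            T += float(self.rng.normal(0.0, p.step_time_jitter_std))
        T = min(max(T, p.t_step_min), p.t_step_max)
        if T <= 0:
            raise ConfigurationError("non-positive step time")
        return T

    def _w_des(self, vtm: float) -> float:
        base = vtm if self.follow_belt else self.p.v_pref
        return base + self.p.k_station * (self.p.station - self.y)

    def tick(self, vtm: float) -> tuple:
        """Advance one sample; returns the raw sensor tuple plus truth.

        ``(fz_l, fy_l, copy_l, fz_r, fy_r, copy_r, truth_p, truth_v)`` --
        truth is the COM state at this sample, sensors cover this sample.
        """
        p = self.p
        dt = self.dt
        self.k += 1
        t = self.k * dt
        if self.k == 0:
            # start mid-gait at the behavioral equilibrium speed
            self.v = self._w_des(vtm) - vtm
            w0 = self.v + vtm
            self.T_cur = self._draw_T(w0)
            self.next_contact = self.T_cur
            self.cur = _Foot(belt="right", pos=self.y, cop_off=self._cop_off())

        if t >= self.next_contact - 1e-12:
            self.step_idx += 1
            w = self.v + vtm
            T_next = self._draw_T(w)
            L = w * T_next
            cross = self.step_idx in p.crossover_steps
            if p.crossover_prob > 0 and not cross:
                cross = bool(self.rng.random() < p.crossover_prob)
            belt = self.cur.belt if cross else (
                "left" if self.cur.belt == "right" else "right")
            foot = _Foot(belt=belt, pos=self.y + 0.5 * L,
                         cop_off=self._cop_off())
            self.prev = self.cur
            self.cur = foot
            self.t_last = t
            self.T_cur = T_next
            self.T_ds = p.double_support_frac * T_next
            self.next_contact = t + T_next
            self.truth_steps.append({
                "step": self.step_idx, "t_place": t, "belt": belt,
                "placement": foot.pos, "w": w, "T": T_next,
                "crossover": cross,
            })

        # load shares (raised-cosine transfer over double support)
        if self.prev is not None:
            tau = t - self.t_last
            if tau < self.T_ds:
                s = 0.5 * (1.0 - math.cos(math.pi * tau / self.T_ds))
            else:
                s = 1.0
                self.prev = None
        else:
            s = 1.0
        share = {"left": 0.0, "right": 0.0}
        share[self.cur.belt] += s
        cop_num = {"left": 0.0, "right": 0.0}
        cop_num[self.cur.belt] += s * (self.cur.pos + self.cur.cop_off)
        if self.prev is not None:
            share[self.prev.belt] += 1.0 - s
            cop_num[self.prev.belt] += (1.0 - s) * (self.prev.pos
                                                    + self.prev.cop_off)
        fz_l = self.mg * share["left"]
        fz_r = self.mg * share["right"]
        copy_l = cop_num["left"] / share["left"] if share["left"] > 0 else float("nan")
        copy_r = cop_num["right"] / share["right"] if share["right"] > 0 else float("nan")

        # COM dynamics: next-sample velocity from the behavior law
        ph = (t + dt - self.t_last) / self.T_cur
        osc = p.osc_amp * math.sin(2.0 * math.pi * ph) if p.osc_amp else 0.0
        v_new = self._w_des(vtm) - vtm + osc
        a = (v_new - self.v) / dt
        f_y = p.mass * (a + self._a_noise[self.k])
        fy_l = f_y * share["left"]
        fy_r = f_y * share["right"]
        truth_p, truth_v = self.y, self.v

        # advance COM with the same discrete kinematics the filter uses
        self.y += self.v * dt + 0.5 * a * dt * dt
        self.v = v_new
        self.cur.pos -= vtm * dt
        if self.prev is not None:
            self.prev.pos -= vtm * dt
        return fz_l, fy_l, copy_l, fz_r, fy_r, copy_r, truth_p, truth_v


def _tick_frame(n: int, fs: float, cols: dict) -> pd.DataFrame:
    data = {"t": np.arange(n) / fs}
    data.update(cols)
    return pd.DataFrame(data)


def synth_trial(walker: WalkerParams,
                profile: Union[str, np.ndarray, Sequence[float]],
                duration: Optional[float] = None,
                seed: int = 0, fs: float = 1000.0,
                follow_belt: bool = True) -> TrialLog:
    """Open-loop trial: scripted belt speed, walker on board, no estimator.

    ``profile`` is a schedule name (see :func:`scripted_profiles`) or a
    belt-speed array at rate ``fs``.  With ``follow_belt`` (default) the
    walker matches its belt-relative speed to the belt, as people do on a
    fixed-speed treadmill; otherwise it holds its preferred speed.
    Deterministic given ``(seed, params)``.
    """
    if isinstance(profile, str):
        if duration is None:
            duration = 60.0
        vtm = scripted_profiles(profile, duration, fs)
        profile_name = profile
    else:
        vtm = np.asarray(profile, float)
        profile_name = "custom"
        if duration is not None and int(round(duration * fs)) != len(vtm):
            raise ConfigurationError("duration inconsistent with profile length")
    n = len(vtm)
    if n < 2 * (walker.c0 - walker.c1 * float(vtm[0])) * fs:
        raise ConfigurationError("trial shorter than two steps")
    rng = np.random.default_rng(seed)
    sim = _WalkerSim(walker, fs, n, rng, follow_belt=follow_belt)
    out = np.empty((n, 8))
    for k in range(n):
        out[k] = sim.tick(float(vtm[k]))
    ticks = _tick_frame(n, fs, {
        "fz_l": out[:, 0], "fy_l": out[:, 1], "copy_l": out[:, 2],
        "fz_r": out[:, 3], "fy_r": out[:, 4], "copy_r": out[:, 5],
        "vtm": vtm, "truth_p": out[:, 6], "truth_v": out[:, 7],
    })
    steps = pd.DataFrame(sim.truth_steps)
    meta = {"kind": "open_loop", "seed": int(seed), "fs": fs,
            "profile": profile_name, "follow_belt": follow_belt,
            "body_mass": walker.mass, "body_weight": walker.body_weight,
            "walker": asdict(walker)}
    return TrialLog(ticks=ticks, steps=steps, meta=meta)


def synth_forces(com_p: np.ndarray, footsteps: pd.DataFrame,
                 walker: WalkerParams, vtm: np.ndarray,
                 fs: float = 1000.0) -> ForcePlateSeries:
    """Force-plate channels for a given COM trajectory and footstep table.

    ``footsteps`` needs columns ``t_place``, ``belt``, ``placement``.  The
    total fore-aft force is mass x the discrete COM acceleration (exact
    Newton consistency before noise); vertical load transfers between belts
    with a raised-cosine profile over the double-support window; each
    foot's COP rides the belt from its placement.  Noise is off here --
    this entry point exists for externally supplied trajectories; the trial
    generators inject noise at synthesis time.
    """
    com_p = np.asarray(com_p, float)
    vtm = np.asarray(vtm, float)
    n = len(com_p)
    dt = 1.0 / fs
    v = np.gradient(com_p, dt)
    a = np.gradient(v, dt)
    f_y = walker.mass * a
    mg = walker.body_weight
    # belt travel with the package's rectangle-rule convention
    travel = np.concatenate(([0.0], np.cumsum(vtm[1:]) / fs))
    rows = footsteps.sort_values("t_place").to_dict("records")
    if len(rows) < 2:
        raise ConfigurationError("need at least two footsteps")
    if rows[0]["t_place"] > dt:
        raise ConfigurationError("footsteps must tile the trajectory "
                                 "(first stance at t=0)")
    for r1, r2 in zip(rows, rows[1:]):
        if r1["belt"] == r2["belt"] and r2["t_place"] - r1["t_place"] < 1e-9:
            raise ConfigurationError("overlapping same-belt stances")
    place_k = [int(round(r["t_place"] * fs)) for r in rows]
    fz = {"left": np.zeros(n), "right": np.zeros(n)}
    copy = {"left": np.full(n, np.nan), "right": np.full(n, np.nan)}
    fy = {"left": np.zeros(n), "right": np.zeros(n)}
    i = 0
    for k in range(n):
        while i + 1 < len(rows) and k >= place_k[i + 1]:
            i += 1
        cur = rows[i]
        k_cur = place_k[i]
        T_step = ((place_k[i + 1] - k_cur) / fs if i + 1 < len(rows)
                  else (k_cur - place_k[i - 1]) / fs)
        T_ds = walker.double_support_frac * T_step
        tau = (k - k_cur) / fs
        if i > 0 and tau < T_ds:
            s = 0.5 * (1.0 - math.cos(math.pi * tau / T_ds))
            prev = rows[i - 1]
        else:
            s, prev = 1.0, None
        share = {"left": 0.0, "right": 0.0}
        num = {"left": 0.0, "right": 0.0}
        pos_cur = cur["placement"] - (travel[k] - travel[k_cur])
        share[cur["belt"]] += s
        num[cur["belt"]] += s * pos_cur
        if prev is not None:
            pos_prev = prev["placement"] - (travel[k] - travel[place_k[i - 1]])
            share[prev["belt"]] += 1.0 - s
            num[prev["belt"]] += (1.0 - s) * pos_prev
        for belt in ("left", "right"):
            if share[belt] > 0:
                fz[belt][k] = mg * share[belt]
                copy[belt][k] = num[belt] / share[belt]
                fy[belt][k] = f_y[k] * share[belt]
    return ForcePlateSeries(
        fs=fs, vtm=vtm,
        fz_l=fz["left"], fy_l=fy["left"], copy_l=copy["left"],
        fz_r=fz["right"], fy_r=fy["right"], copy_r=copy["right"],
        body_mass=walker.mass, body_weight=walker.body_weight)


def closed_loop(walker: WalkerParams,
                filter_params: Optional[est.FilterParams] = None,
                controller_params: Optional[ctl.ControllerParams] = None,
                duration: float = 60.0, seed: int = 0,
                lowpass_order: int = 3, lowpass_fc: float = 25.0) -> TrialLog:
    """Self-paced trial: estimator and controller in the loop.

    The belt starts at the controller's ``v_start`` (0.8 m/s).  Every
    sample the walker advances and its forces feed the streaming estimator;
    at every accepted footstep the controller issues a speed/acceleration
    command which the belt model executes.  Returns the full synchronized
    log (truth, sensors, estimates, commands).
    """
    fp_params = filter_params or est.FilterParams()
    cp = controller_params or ctl.ControllerParams()
    fs = 1.0 / fp_params.dt
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    sim = _WalkerSim(walker, fs, n, rng, follow_belt=False)
    belt = TreadmillModel(v=cp.v_start)
    pipe = est.OnlineEstimator(fp_params, walker.mass, walker.body_weight,
                               fs, lowpass_order, lowpass_fc)
    out = np.empty((n, 8))
    vtm_log = np.empty(n)
    p_kf = np.empty(n)
    v_kf = np.empty(n)
    results = []
    commands = []
    st = pipe.state
    dt = fp_params.dt
    for k in range(n):
        vtm = belt.v
        vtm_log[k] = vtm
        row = sim.tick(vtm)
        out[k] = row
        _, res = pipe.tick(row[0], row[1], row[2], row[3], row[4], row[5],
                           vtm)
        if res is not None:
            results.append(res)
            cmd = ctl.update_on_contact(res, cp)
            commands.append(cmd)
            if cmd is not None:
                belt.apply(cmd)
        p_kf[k] = st.p_kf
        v_kf[k] = st.v_kf
        belt.tick(dt)
    ticks = _tick_frame(n, fs, {
        "fz_l": out[:, 0], "fy_l": out[:, 1], "copy_l": out[:, 2],
        "fz_r": out[:, 3], "fy_r": out[:, 4], "copy_r": out[:, 5],
        "vtm": vtm_log, "truth_p": out[:, 6], "truth_v": out[:, 7],
        "p_kf": p_kf, "v_kf": v_kf,
    })
    steps = est._steps_frame(results)
    cmd_rows = [c for r, c in zip(results, commands) if r.meas is not None]
    if len(steps):
        steps["cmd_v"] = [c.v_tgt if c else np.nan for c in cmd_rows]
        steps["cmd_a"] = [c.a_tgt if c else np.nan for c in cmd_rows]
        steps = est._truth_step_means(steps, ticks, fs)
    meta = {"kind": "closed_loop", "seed": int(seed), "fs": fs,
            "duration": duration, "body_mass": walker.mass,
            "body_weight": walker.body_weight,
            "n_rejected": pipe.n_rejected,
            "n_commands": int(sum(c is not None for c in commands)),
            "walker": asdict(walker), "controller": asdict(cp)}
    return TrialLog(ticks=ticks, steps=steps, meta=meta)
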