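# Methods

## The estimation problem

On a treadmill whose belt speed changes, the walker's speed and station
cannot be read from any single sensor: integrating the fore-aft ground
reaction force (GRF) gives smooth but drifting estimates (any force bias or
noise integrates into unbounded position error), while foot-placement
geometry gives accurate but sparse, noisy per-step measurements.  The
package fuses the two in a Kalman filter on the state `x = [p, v]` (lab
frame fore-aft position and velocity): per-sample prediction from
`a_mes = f_y/m`, per-footstep correction from the step measurements.

Conventions: +y is the walker's forward direction, origin at the treadmill
center; `v_tm ≥ 0` is the belt-surface speed, the surface moving in −y.  A
foot resting on the belt therefore translates by `−∫v_tm dt`, which fixes
the sign of the trailing-foot reconstruction `y_f0 = COP₀ − ∫v_tm dt`; this
sign is what makes step length equal belt travel for a walker with no lab
drift, and makes the plus-sign control law negative feedback.

## Signal conditioning and contact detection

Force channels pass through a causal third-order Butterworth low-pass at
25 Hz (unit DC gain; the streaming form is initialized at steady state for
the first sample, so constants pass untouched).  The COP is *not* filtered
directly: the ratio is ill-behaved as a belt unloads.  Instead the fore-aft
moment proxy `f_z·cop_y` and `f_z` are filtered and re-divided, and the
result is marked invalid wherever filtered `f_z` is below 5% of body
weight.

Contacts are rising crossings of filtered `f_z` through 20% of body
weight.  A belt re-arms only after dropping below 10% of body weight
(hysteresis against chatter); if both belts cross in the same sample, the
more-loaded belt wins.  Steps shorter than 0.2 s are rejected as
re-triggers, steps longer than 1.2 s as belt crossovers; rejected steps
skip the measurement update and issue no belt command, but still become the
reference contact for the next step, and the step-mean accumulators reset
at every contact either way.

## Filter constants

| constant | value | meaning |
|---|---|---|
| Δt | 0.001 s | sample period (1 kHz plates) |
| σ_a² | 2.9 (m/s²)² | process (acceleration) noise; additive term σ_a²·B·Bᵀ |
| R | 10⁻³·diag(0.6, 7.2) | variance of (p̄_mes, v̄_mes); σ_p ≈ 0.024 m, σ_v ≈ 0.085 m/s |
| P0 | 10⁻³·[[3.5, 1.5],[1.5, 1.6]] | initial error covariance |

These are empirical values for human treadmill walking at 0.8–1.8 m/s,
obtained by comparing force-plate measurements against motion capture; the
package treats them as given defaults, all overridable.  The innovation
uses the running *means* of the predicted state since the last contact
(matching what the step measurements actually measure) while the
correction is applied to the instantaneous state; the covariance update is
`(I−K)P`, symmetrized.  The filter state initializes to zero with `P = P0`;
no correction happens before the second detected contact.

## Controller

`v_tm,tgt = v̄_tm + G_v·v̄_KF + G_p·(p̄_KF − p_0)` with `G_v = 0.25`,
`G_p = 0.1 s⁻¹`, clamped to [0, 2.5] m/s (the belt never reverses);
`a_tm,tgt = (v_tm,tgt − v̄_tm)/0.5 s`, clamped to ±2 m/s².  `v̄_tm` is the
measured mean belt speed over the completed step, not the last commanded
target.  Unit gains would match the walker's speed exactly and re-center
within a second, but feel abrupt; the soft defaults trade response speed
for comfort.  `p_0` defaults to 0 and is normally calibrated as the mean
*estimated* position during fixed-speed walking — important, because the
estimator's position is referenced to foot placements, not to any anatomical
landmark (see Limitations).

## The virtual walker

The simulator's load-bearing property is consistency with the measurement
model, not biomechanical realism:

* **Fore-aft force** is exactly `mass × COM acceleration` at every sample
  (before sensor noise), with the COM advanced by the same discrete
  kinematics the filter assumes, so integrating `f_y/m` reproduces the COM
  trajectory to numerical precision.
* **Behavior law**: the walker steers its belt-relative speed toward a
  preferred speed `v_pref` (or toward the belt speed, in scripted
  fixed-speed trials — people on a fixed-speed treadmill walk at belt
  speed) plus a weak station-keeping correction `k_station·(station − y)`,
  `k_station = 0.1 s⁻¹` by default, which gives the closed loop a unique
  equilibrium.  A within-step sinusoidal speed oscillation (default
  0.15 m/s amplitude) emulates the natural speed fluctuation of gait.
* **Footsteps** alternate belts; step time follows `T = c0 − c1·w`
  (defaults `c0 = 0.8 s`, `c1 = 0.2 s²/m`, clamped to [0.3, 1.5] s — about
  0.54 s at 1.3 m/s, a plausible human cadence; the constants are package
  choices, not fitted claims).  Each foot lands half a step length ahead of
  the COM and rides the belt; vertical load transfers to it over a
  raised-cosine double-support window (default 20% of the step), so the
  total always sums to body weight.  Vertical COM dynamics are omitted:
  `f_z` carries no information the estimator uses beyond contact timing.
* **Crossover steps** (forced via `inject_crossover` or drawn with
  `crossover_prob`) place the new foot on its predecessor's belt; the plate
  never unloads, no threshold crossing occurs, and the detector sees one
  double-length inter-contact interval — the signature the 1.2-s rule
  exists to reject.
* **Sensor noise** enters at the sensor level so R keeps its meaning:
  white acceleration-equivalent noise on the force channels (default
  1.7 m/s², the filter's own assumed process noise), a constant per-stance
  offset on each foot's COP reading (default 0.024 m ≈ σ_p), and Gaussian
  step-time jitter (default 0.02 s).  Because the COP error is per stance
  and two placements enter each measurement, a single
  `σ_cop = √2·σ_p ≈ 0.035 m` makes *both* step-measurement scatters match
  the printed R diagonal (`σ_p` for position; `√2σ_cop/T ≈ 0.09 m/s ≈ σ_v`
  for speed at a 0.55-s step) — the setting used in the noise-calibrated
  verification runs.

The treadmill model ramps continuously toward the commanded speed at the
commanded |acceleration| and holds on arrival.

## Evaluation metrics

* `rms_step_errors`: step-aligned RMS of speed differences; position
  differences lose their per-trial mean first (the estimator's position
  datum is arbitrary).  Offset correction is idempotent and the RMS is
  invariant under step reordering / constant position shifts.
* `convergence_time` / `convergence_distance`: band = mean ± max(SD, ε) of
  the last 20% of trial time (or last 30 m of distance), ε = 10⁻³ m/s
  guarding degenerate zero-SD tails; the statistic is the first band entry.
  The speed series used is the per-step walking speed
  `v̄_tm + v̄_KF`, zero-order-held between footsteps.
* `section_speeds`: distance/time over fixed 10-m sections, by default
  centered in six equal subdivisions of a 150-m course.
* `linear_fit_corr` (least squares + Pearson R/p via scipy) and
  `intra_subject_sd` (sample SD, n−1 denominator) for cohort-style
  comparisons.

## Numerical and design choices

* The covariance propagation is written in closed 2×2 scalar form (exact,
  and fast enough to run the 1-kHz loop in pure Python); `(P+R)` inversion
  uses the cofactor formula with a positive-definiteness assertion.
* Offline replay drives the same streaming pipeline (`OnlineEstimator`)
  sample by sample, so offline and online results are identical by
  construction; the streaming low-pass reproduces `scipy.signal.lfilter`'s
  recursion exactly.
* Belt travel between contacts uses a rectangle rule at the sampling rate,
  and the same sum defines `v̄_tm`, so the step-speed identity
  `v̄_mes = (y_f1−y_f0)/(t1−t0) − v̄_tm` holds to machine precision.
* Deterministic runs: all simulator randomness flows from one
  `numpy.random.Generator`; identical (seed, params) give bit-identical
  trials.  Noise draws are skipped entirely when a noise std is zero, so
  zeroing one source does not shift the others' streams... it does change
  the stream layout, which is why determinism is defined per (seed,
  params).

Verification problem sizes: 60-s trials at 1 kHz for the tracking and
closed-loop checks, 20 seeds for the noise-calibrated batch, 100 seeds for
the divergence statistic, 10-update instances for the batch-Gaussian
oracle — sizes at which every quantity is stable at the tolerances tested.

## What passing tests do and do not show

The simulator satisfies the estimator's model assumptions by construction
(exact Newton consistency, point-foot COP, stationary noise).  Passing the
verification suite therefore shows the *algorithm* is implemented
correctly and behaves as designed under its own assumptions.  It does not
show robustness to what real gait adds: vertical COM dynamics coupling
into `f_z` timing, heel-to-toe COP progression within stance, force-plate
crosstalk and drift, asymmetric or variable gait, or human responses to
belt accelerations beyond first-order station-keeping.

## Known limitations

* The per-footstep correction uses step means but corrects the
  instantaneous state with the instantaneous-state gain; this is the
  published recursion, not the Bayes-optimal filter for mean observations.
  The batch-oracle equivalence is therefore exact only when a measurement
  window is one sample long, and that is how the oracle check is framed.
* The position estimate is referenced to foot placements and sits at a
  speed-dependent constant offset (≈`v_tm` × the loading delay to the 20%
  threshold, a few cm) from the COM.  Calibrating `p_0` in the same
  measure absorbs it; comparisons against COM ground truth need the offset
  correction.  Locking the zero-initialized state onto this datum takes
  the filter a few footsteps and briefly couples into the speed estimate
  through P0's off-diagonal — visible as a ~0.02–0.05 m/s transient over
  the first ~3 corrections of any trial.
* A cold-started causal filter misses pre-trial acceleration history; with
  the within-step oscillation on, this adds a small decaying speed offset
  over the first seconds.  Both startup effects are excluded by a 5-s
  lock-in window wherever a per-step exactness bound is asserted.
* Crossover handling assumes the merged stance produces *no* crossing on
  the contralateral plate; partial crossovers (foot straddling both belts)
  are not modeled.
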