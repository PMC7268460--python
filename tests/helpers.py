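"""Independent oracles for the test suite.

Everything here is written against the mathematical definitions, not the
package's code paths, so agreement is evidence rather than tautology.
"""

import numpy as np
from scipy import signal


def batch_gaussian_posterior(A, B, Q, P0, R, accels, meas_ticks, zs):
    """Posterior mean of the final state by joint-Gaussian conditioning.

    States ``x_0 .. x_N`` follow ``x_{k+1} = A x_k + B a_k + w_k`` with
    ``x_0 ~ N(0, P0)`` and ``w_k ~ N(0, Q)``.  Measurements ``z_j = x_{k_j}
    + v_j`` with ``v_j ~ N(0, R)`` observe the state directly.  The
    conditional mean of ``x_N`` given all ``z`` is computed by building the
    full joint covariance of ``(x_N, z_1..z_m)`` -- no filtering recursion
    anywhere.
    """
    N = len(accels)
    d = A.shape[0]
    # prior means
    means = [np.zeros(d)]
    for k in range(N):
        means.append(A @ means[-1] + B * accels[k])
    # covariance of every pair of states via the noise decomposition
    powers = [np.eye(d)]
    for _ in range(N):
        powers.append(A @ powers[-1])

    def cov(k, l):
        c = powers[k] @ P0 @ powers[l].T
        for j in range(min(k, l)):
            c += powers[k - 1 - j] @ Q @ powers[l - 1 - j].T
        return c

    m = len(meas_ticks)
    Szz = np.zeros((d * m, d * m))
    SxNz = np.zeros((d, d * m))
    mz = np.zeros(d * m)
    for i, ki in enumerate(meas_ticks):
        mz[d * i:d * i + d] = means[ki]
        SxNz[:, d * i:d * i + d] = cov(N, ki)
        for j, kj in enumerate(meas_ticks):
            blk = cov(ki, kj)
            if i == j:
                blk = blk + R
            Szz[d * i:d * i + d, d * j:d * j + d] = blk
    zvec = np.concatenate(zs)
    return means[N] + SxNz @ np.linalg.solve(Szz, zvec - mz)


def reference_offline_pipeline(series, dt=1e-3, sigma_a2=2.9,
                               R=None, P0=None, fc=25.0, order=3,
                               thr_frac=0.2, rearm_frac=0.1,
                               floor_frac=0.05, max_step=1.2, min_step=0.2):
    """A second, independent implementation of the full estimation loop.

    Vectorized filtering with scipy.lfilter, an explicit hysteresis scan
    for contacts, and a matrix-form Kalman recursion.  Returns per-tick
    ``(p, v)`` and the per-step table as plain arrays.
    """
    if R is None:
        R = np.diag([0.6e-3, 7.2e-3])
    if P0 is None:
        P0 = 1e-3 * np.array([[3.5, 1.5], [1.5, 1.6]])
    fs = series.fs
    b, a = signal.butter(order, fc, btype="low", fs=fs)

    def filt(x):
        zi = signal.lfilter_zi(b, a) * x[0]
        return signal.lfilter(b, a, x, zi=zi)[0]

    bw = series.body_weight
    mass = series.body_mass
    fz = {s: filt(getattr(series, f"fz_{s}")) for s in "lr"}
    fy = {s: filt(getattr(series, f"fy_{s}")) for s in "lr"}
    mom = {s: filt(getattr(series, f"fz_{s}")
                   * np.nan_to_num(getattr(series, f"copy_{s}")))
           for s in "lr"}
    with np.errstate(divide="ignore", invalid="ignore"):
        cop = {s: np.where(fz[s] >= floor_frac * bw, mom[s] / fz[s], np.nan)
               for s in "lr"}
    a_mes = (fy["l"] + fy["r"]) / mass

    # contact scan with hysteresis
    thr, lo = thr_frac * bw, rearm_frac * bw
    events = []  # (k, side)
    armed = {s: fz[s][0] <= thr for s in "lr"}
    n = series.n
    for k in range(n):
        crossing = [s for s in "lr" if armed[s] and fz[s][k] > thr]
        for s in "lr":
            if not armed[s] and fz[s][k] < lo:
                armed[s] = True
        if crossing:
            if len(crossing) == 2:
                win = "l" if fz["l"][k] >= fz["r"][k] else "r"
            else:
                win = crossing[0]
            for s in crossing:
                armed[s] = False
            events.append((k, win))

    A = np.array([[1.0, 1.0 / fs], [0.0, 1.0]])
    Bv = np.array([0.5 / fs ** 2, 1.0 / fs])
    Q = sigma_a2 * np.outer(Bv, Bv)
    x = np.zeros(2)
    P = P0.copy()
    travel = np.concatenate(([0.0], np.cumsum(series.vtm[1:]) / fs))
    p_out = np.empty(n)
    v_out = np.empty(n)
    acc = []
    prev = None  # (k, cop)
    steps = []
    ev_idx = 0
    for k in range(n):
        x = A @ x + Bv * a_mes[k]
        P = A @ P @ A.T + Q
        acc.append(x.copy())
        if ev_idx < len(events) and events[ev_idx][0] == k:
            kk, side = events[ev_idx]
            ev_idx += 1
            c = cop[side][k]
            if prev is not None:
                sd = (k - prev[0]) / fs
                tr = travel[k] - travel[prev[0]]
                yf0 = prev[1] - tr
                yf1 = c
                vbar_tm = tr / sd
                vmes = (yf1 - yf0) / sd - vbar_tm
                pmes = 0.5 * (yf1 + yf0)
                ok = min_step <= sd <= max_step and np.isfinite(vmes + pmes)
                if ok:
                    zbar = np.array([pmes, vmes])
                    xbar = np.mean(acc, axis=0)
                    K = P @ np.linalg.inv(P + R)
                    x = x + K @ (zbar - xbar)
                    P = (np.eye(2) - K) @ P
                    P = 0.5 * (P + P.T)
                steps.append((prev[0] / fs, k / fs, vmes, pmes, vbar_tm, ok))
            acc = []
            prev = (k, c)
        p_out[k] = x[0]
        v_out[k] = x[1]
    return p_out, v_out, steps
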