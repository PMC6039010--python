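import numpy as np
import pytest

import phaselag as pl

TWO_PI = 2.0 * np.pi


@pytest.fixture(scope="session")
def fig1a():
    """Two identical noisy oscillators (12 Hz, tau=0.01 s, K=30, D=5),
    100 s, with windowed PLV and both surrogate thresholds."""
    net = pl.pair_network(12 * TWO_PI, 12 * TWO_PI, K=30.0, tau=0.01, D=5.0)
    traj = pl.integrate(net, 100.0, seed=42, warmup=pl.default_warmup(net))
    op = pl.order_parameters(traj, net)
    f_ent = abs(float(np.mean(op.Omega_inst))) / TWO_PI
    res = pl.sliding_cplv(traj, f_ent)
    thr_shuffle = pl.significance_threshold(traj, "shuffle", f_ent, seed=7)
    thr_unc = pl.significance_threshold(traj, "uncoupled", f_ent, seed=7)
    res = pl.lag_statistics(res, thr_shuffle)
    return dict(net=net, traj=traj, op=op, f_ent=f_ent, res=res,
                thr_shuffle=thr_shuffle, thr_uncoupled=thr_unc)


@pytest.fixture(scope="session")
def fig1b():
    """Detuned pair (12*[0.95, 1.05] Hz), otherwise as fig1a."""
    w1, w2 = 12 * 0.95 * TWO_PI, 12 * 1.05 * TWO_PI
    net = pl.pair_network(w1, w2, K=30.0, tau=0.01, D=5.0)
    traj = pl.integrate(net, 100.0, seed=11, warmup=pl.default_warmup(net))
    op = pl.order_parameters(traj, net)
    f_ent = abs(float(np.mean(op.Omega_inst))) / TWO_PI
    res = pl.sliding_cplv(traj, f_ent)
    thr = pl.significance_threshold(traj, "shuffle", f_ent, seed=11)
    res = pl.lag_statistics(res, thr)
    return dict(net=net, traj=traj, op=op, f_ent=f_ent, res=res,
                omega=(w1, w2))


def brute_pair(w1, w2, K, tau, t_final, dt, theta0):
    """Independent brute-force Heun integrator for a batch of two-oscillator
    initial conditions (B x 2), written without the package's machinery.

    Returns (locked frequency per IC, wrapped phase difference per IC),
    both measured over the final 20% of the run.
    """
    theta0 = np.atleast_2d(np.asarray(theta0, dtype=float))
    B = theta0.shape[0]
    lag = int(round(tau / dt))
    n = int(round(t_final / dt))
    buf = np.empty((lag + 2, B, 2))
    for k in range(lag + 1):
        buf[(-k) % (lag + 2)] = theta0 - np.array([w1, w2]) * k * dt
    th = theta0.copy()
    om = np.array([w1, w2])
    n_tail = max(2, n // 5)
    tail = np.empty((n_tail, B, 2))
    ti = 0

    def f(state, slot):
        d = buf[(slot - lag) % (lag + 2)] if lag else state
        drive = np.empty_like(state)
        drive[:, 0] = -K * np.sin(state[:, 0] - d[:, 1])
        drive[:, 1] = -K * np.sin(state[:, 1] - d[:, 0])
        return om + drive

    for s in range(n):
        f0 = f(th, s)
        pred = th + dt * f0
        buf[(s + 1) % (lag + 2)] = pred
        f1 = f(pred, s + 1)
        th = th + 0.5 * dt * (f0 + f1)
        buf[(s + 1) % (lag + 2)] = th
        if s >= n - n_tail:
            tail[ti] = th
            ti += 1
    span = (n_tail - 1) * dt
    freq = (tail[-1] - tail[0]) / span          # B x 2
    phi = np.angle(np.exp(1j * (tail[-1, :, 0] - tail[-1, :, 1])))
    return freq, phi
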