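"""Windowed PLV with surrogate significance on a noisy locked pair.

Two identical 12 Hz oscillators with tau = 10 ms, K = 30, D = 5 are
integrated for 60 s; the complex PLV is computed on sliding windows of 10
entrainment periods (75% overlap) and windows are kept above the
shuffle-surrogate and uncoupled-surrogate significance levels.
"""

import numpy as np

import phaselag as pl

TWO_PI = 2 * np.pi
net = pl.pair_network(12 * TWO_PI, 12 * TWO_PI, K=30.0, tau=0.01, D=5.0)
traj = pl.integrate(net, 60.0, seed=2, warmup=pl.default_warmup(net))

op = pl.order_parameters(traj, net)
f_ent = abs(float(np.mean(op.Omega_inst))) / TWO_PI
print(f"mean entrainment frequency: {f_ent:.2f} Hz "
      f"(depressed below the 12 Hz natural frequency by the delay)")

res = pl.sliding_cplv(traj, f_ent)
thr_lo = pl.significance_threshold(traj, "shuffle", f_ent, seed=3)
thr_hi = pl.significance_threshold(traj, "uncoupled", f_ent, seed=3)
res = pl.lag_statistics(res, thr_lo)
n_sig = int(res.significant[:, 0, 1].sum())
print(f"windows: {res.n_windows}, significant (shuffle level "
      f"{thr_lo:.3f}): {n_sig}, uncoupled level: {thr_hi[0, 1]:.3f} "
      f"(stricter)")
print(f"circular mean lag {res.circ_mean[0, 1]:+.3f} rad, "
      f"circular SD {res.circ_sd[0, 1]:.3f} rad")
print("identical oscillators lock in-phase: the mean lag is ~0; only the")
print("dispersion, not the mean, depends on the chosen significance level")
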