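"""Locked states of two delay-coupled oscillators: theory vs simulation.

Builds a detuned pair (11.4 and 12.6 Hz, tau = 10 ms, K = 30), solves the
transcendental locking equations for every root, then integrates the
noise-free dynamics and checks which root the system selects.
"""

import numpy as np

import phaselag as pl

TWO_PI = 2 * np.pi
w1, w2 = 11.4 * TWO_PI, 12.6 * TWO_PI
K, tau = 30.0, 0.01

print("roots of the locking equations (Omega rad/s, phi rad):")
for s in pl.sync_frequency_two(w1, w2, K, tau):
    print(f"  Omega={s.Omega:7.3f}  phi={s.phi:+.3f}  {s.regime:10s} "
          f"stable={s.stable}  Kc={s.Kc:.2f}")

net = pl.pair_network(w1, w2, K=K, tau=tau)
traj = pl.integrate(net, 30.0, seed=1)
Om = float((traj.theta[0, -1] - traj.theta[0, -100])
           / (traj.times[-1] - traj.times[-100]))
phi = float(np.angle(np.exp(1j * (traj.theta[0, -1] - traj.theta[1, -1]))))
print(f"\nsimulation locks at Omega={Om:.3f} rad/s with phi={phi:+.3f} rad")
print("(the locked frequency sits below the mean natural frequency —")
print(" delay-induced frequency depression — and the slower oscillator")
print(" lags: phi < 0 because omega_1 < omega_2)")
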