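"""Oscillatory dynamics on a synthetic two-hemisphere connectome.

Generates a 68-region connectome (bimodal tract lengths: ~50 mm within
and ~130 mm between hemispheres; log-normal weights, weaker between
hemispheres), derives delays at 5 m/s, and simulates 6 Hz oscillators
with global coupling K = 0.8 and noise D = 0.5.
"""

import numpy as np

import phaselag as pl

TWO_PI = 2 * np.pi
con = pl.synth_connectome(N=68, seed=1)
tau = con.taumat
print(f"synthetic connectome: {con.N} regions, delays "
      f"{tau[tau > 0].min() * 1e3:.1f}-{tau.max() * 1e3:.1f} ms at 5 m/s "
      f"(bimodal: intra ~{np.median(tau[con.intra_mask]) * 1e3:.0f} ms, "
      f"inter ~{np.median(tau[con.inter_mask]) * 1e3:.0f} ms)")

net = pl.connectome_network(con, K=0.8, f_hz=6.0, D=0.5)
traj = pl.integrate(net, 120.0, seed=1, warmup=20.0)
op = pl.order_parameters(traj, net)
Om = float(np.mean(op.Omega_inst))
print(f"coherence r={op.r.mean():.3f}; locked frequency "
      f"{Om / TWO_PI:.2f} Hz vs natural 6 Hz (frequency depression)")

mf = np.unwrap(np.angle(np.exp(1j * traj.theta).mean(axis=0)))
phi = np.angle(np.exp(1j * (traj.theta - mf)).mean(axis=1))
c = np.corrcoef(net.strengths, phi)[0, 1]
print(f"strength-phase correlation: {c:+.3f}")
print("negative: during frequency depression the strongly connected")
print("regions phase-lag behind the weakly connected ones")
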