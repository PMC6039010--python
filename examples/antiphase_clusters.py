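"""Anti-phase synchronization of delay-imposed clusters.

Two clusters of 150 oscillators each: intra-cluster delays 0.04 s,
inter-cluster 0.27 s, K = 7, Lorentzian frequencies (1 Hz, gamma = 1).
For these delays the inter-cluster angle Omega*tau_2 falls in the left
complex half-plane, so the cluster mean fields lock a distance pi apart
at a frequency above the natural one.
"""

import numpy as np

import phaselag as pl
from phaselag.model import DelaySpec, FrequencySpec, StrengthSpec

TWO_PI = 2 * np.pi
d = DelaySpec(kind="bimodal_clustered", tau1=0.04, tau2=0.27)

for s in pl.sync_frequency_network(TWO_PI, 1.0, 7.0, d, "clustered"):
    print(f"root: Omega={s.Omega:.3f}, r={s.r:.3f}, {s.regime}, "
          f"psi2={s.psi2:.2f}, stable={s.stable}")

oa = pl.oa_integrate(TWO_PI, 1.0, 7.0, d, "clustered", z0=[0.5, -0.5],
                     t_final=150.0)
off = abs(np.angle(oa.z[0][-1] * np.conj(oa.z[1][-1])))
print(f"OA integration from an anti-symmetric start: r={oa.r_steady:.3f}, "
      f"Omega={oa.Omega_steady:.3f}, cluster offset={off:.3f} rad")

net = pl.build_network(300, FrequencySpec(kind="lorentzian", mu=TWO_PI,
                                          gamma=1.0),
                       StrengthSpec(K=7.0), d, D=0.0, seed=2)
th0 = np.random.default_rng(2).uniform(-0.5, 0.5, 300)
th0[150:] += np.pi
traj = pl.integrate(net, 120.0, theta0=th0, seed=2, warmup=20.0)
op = pl.order_parameters(traj, net)
reg = pl.detect_regime(op)
dist = np.abs(np.angle(np.exp(1j * (op.Phi_cluster[0]
                                    - op.Phi_cluster[1]))))
print(f"simulation: mean cluster distance {dist.mean():.3f} rad "
      f"(pi = {np.pi:.3f}); anti-phase fraction "
      f"{np.mean(reg.label[reg.defined] == 'anti_phase'):.2f}")
print("the pi offset between the cluster mean fields is the anti-phase")
print("regime: within each cluster lags still follow the in-phase rules")
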