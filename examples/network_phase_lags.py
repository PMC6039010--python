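"""Phase lags on a network with random bimodal delays.

300 identical noisy oscillators (1 Hz), log-normal node strengths
(mean 6, SD 12), each link delayed by 0.02 s or 0.37 s at random.  The
Ott-Antonsen reduction predicts the locked frequency and coherence; the
arcsine law predicts each entrained node's phase from its strength, and a
direct simulation confirms both.
"""

import numpy as np

import phaselag as pl
from phaselag.model import DelaySpec, FrequencySpec, StrengthSpec
from phaselag.theory_network import SyncSolution, quadrant

TWO_PI = 2 * np.pi
d = DelaySpec(kind="bimodal_random", tau1=0.02, tau2=0.37)

sols = pl.sync_frequency_network(TWO_PI, 1.0, 6.0, d, "random")
for s in sols:
    print(f"mean-field root: Omega={s.Omega:.3f} rad/s, r={s.r:.3f}, "
          f"{s.regime}, stable={s.stable}")

net = pl.build_network(300, FrequencySpec(kind="constant", mu=TWO_PI),
                       StrengthSpec(kind="lognormal", m=6.0, s=144.0),
                       d, D=0.1, seed=5)
traj = pl.integrate(net, 120.0, seed=5, warmup=30.0)
op = pl.order_parameters(traj, net)
Om, r = float(np.mean(op.Omega_inst)), float(op.r.mean())
print(f"simulation: Omega={Om:.3f} rad/s, r={r:.3f}")

na, nb = pl.normalize_angles(Om * d.tau_mean, Om * d.tau_halfdiff)
sol = SyncSolution(Omega=Om, r=r, regime="in_phase", psi2=0.0, stable=True,
                   quadrants=(quadrant(Om * d.tau1)[0],
                              quadrant(Om * d.tau2)[0]),
                   tau_mean_angle=na, tau_halfdiff_angle=nb)
pred = pl.relative_phases(net.strengths, TWO_PI, sol)
mf = np.unwrap(np.angle(np.exp(1j * traj.theta).mean(axis=0)))
phi_sim = np.angle(np.exp(1j * (traj.theta - mf)).mean(axis=1))
m = pred.entrained
cc = np.corrcoef(pred.phi[m], phi_sim[m])[0, 1]
print(f"entrained nodes: {m.sum()}/300; predicted-vs-simulated phase "
      f"correlation: {cc:.3f}")
print("with Omega < mu (frequency depression) stronger nodes phase-lag:")
print(f"  strength-phase correlation = "
      f"{np.corrcoef(net.strengths[m], phi_sim[m])[0, 1]:+.3f}")
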