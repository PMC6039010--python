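"""Phase-locked states of two delay-coupled phase oscillators.

For theta_1,2' = omega_1,2 - K sin(theta_1,2(t) - theta_2,1(t - tau)) a
locked state rotates at a common frequency Omega with constant shift
phi = theta_1 - theta_2.  Summing and subtracting the locked equations gives

    Omega = (omega_1 + omega_2)/2 - K sin(Omega tau) cos(phi),
    sin(phi) = (omega_1 - omega_2) / (2 K cos(Omega tau)),

a transcendental system that is generally multistable.  A root is stable
when K cos(Omega tau) cos(phi) > 0 (linearization of the phase-difference
dynamics); its regime is in-phase (|phi| < pi/2) when K cos(Omega tau) > 0
and anti-phase otherwise.  The critical coupling for locking is
Kc = |omega_2 - omega_1| / |2 cos(Omega tau)|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModulationSpec

__all__ = [
    "PairSolution",
    "EffectiveParams",
    "sync_frequency_two",
    "phase_shift_two",
    "critical_coupling_two",
    "effective_params",
]

_SCAN_POINTS = 2000
_BISECT_TOL = 1e-10


class NoLockingError(ValueError):
    """The requested locked state does not exist (|arcsin argument| > 1)."""


@dataclass(frozen=True)
class PairSolution:
    Omega: float          # locked frequency, rad/s
    phi: float            # theta_1 - theta_2, in (-pi/2, 3pi/2]
    regime: str           # "in_phase" | "anti_phase"
    stable: bool
    Kc: float             # critical coupling at this Omega


@dataclass
class EffectiveParams:
    times: np.ndarray
    K_eff: np.ndarray          # (K + eps_K sin w^_K t) cos(Omega tau)
    omega_eff: np.ndarray      # 2 x M effective natural frequencies
    delta_omega_eff: np.ndarray
    locked_predictor: np.ndarray   # |2 K_eff| > |d omega_eff|


def _phi_branch(x: float, branch: str) -> float:
    """phi on the principal (cos phi > 0) or reflected (cos phi < 0) branch."""
    a = float(np.arcsin(x))
    return a if branch == "principal" else np.pi - a


def _residual(Omega: float, mean: float, dw: float, K: float, tau: float,
              branch: str) -> float | None:
    c = np.cos(Omega * tau)
    denom = 2.0 * K * c
    if denom == 0.0:
        return None
    x = dw / denom
    if abs(x) > 1.0:
        return None
    phi = _phi_branch(x, branch)
    return mean - K * np.sin(Omega * tau) * np.cos(phi) - Omega


def sync_frequency_two(omega1: float, omega2: float, K: float,
                       tau: float) -> list[PairSolution]:
    """All locked states on the scan interval [mean - K, mean + K].

    Both arcsine branches of phi are scanned; each sign change of the
    self-consistency residual is bisected to 1e-10.  Multistable sets are
    returned in full, sorted by Omega.
    """
    if K <= 0:
        raise ValueError("K must be > 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    mean = 0.5 * (omega1 + omega2)
    dw = omega1 - omega2
    if tau == 0.0:
        # single root Omega = mean exactly
        sols = []
        for branch in ("principal", "reflected"):
            x = dw / (2.0 * K)
            if abs(x) > 1.0:
                continue
            phi = _phi_branch(x, branch)
            stable = K * np.cos(phi) > 0
            regime = "in_phase" if branch == "principal" else "anti_phase"
            sols.append(PairSolution(mean, phi, regime, stable,
                                     abs(dw) / 2.0))
        if not sols:
            raise NoLockingError("K below the critical coupling |dw|/2")
        return sols

    grid = np.linspace(mean - K, mean + K, _SCAN_POINTS)
    sols: list[PairSolution] = []
    for branch in ("principal", "reflected"):
        vals = [_residual(w, mean, dw, K, tau, branch) for w in grid]
        for i in range(len(grid) - 1):
            a, b = vals[i], vals[i + 1]
            if a is None or b is None or a * b > 0:
                continue
            lo, hi, fa = grid[i], grid[i + 1], a
            while hi - lo > _BISECT_TOL:
                mid = 0.5 * (lo + hi)
                fm = _residual(mid, mean, dw, K, tau, branch)
                if fm is None:
                    break
                if fa * fm <= 0:
                    hi = mid
                else:
                    lo, fa = mid, fm
            Omega = 0.5 * (lo + hi)
            c = np.cos(Omega * tau)
            if abs(2.0 * K * c) < 1e-300:
                continue
            phi = _phi_branch(dw / (2.0 * K * c), branch)
            stable = K * c * np.cos(phi) > 0
            # phi in (-pi/2, pi/2) <=> in-phase; for stable roots this
            # coincides with the sign of K cos(Omega tau)
            regime = "in_phase" if branch == "principal" else "anti_phase"
            Kc, _ = critical_coupling_two(omega1, omega2, tau, Omega)
            if not any(abs(s.Omega - Omega) < 1e-6 and s.regime == regime
                       for s in sols):
                sols.append(PairSolution(float(Omega), float(phi), regime,
                                         bool(stable), Kc))
    if not sols:
        raise NoLockingError(
            "no locked state found on the scan interval; K may be below Kc")
    return sorted(sols, key=lambda s: s.Omega)


def phase_shift_two(omega1: float, omega2: float, K: float, tau: float,
                    Omega: float) -> tuple[float, str]:
    """Phase shift phi = theta_1 - theta_2 at a given locked frequency.

    Returns (phi, regime) with phi on the branch demanded by the sign of
    K cos(Omega tau): (-pi/2, pi/2) in-phase, (pi/2, 3pi/2) anti-phase.
    """
    c = np.cos(Omega * tau)
    denom = 2.0 * K * c
    if denom == 0.0:
        raise NoLockingError("cos(Omega tau) = 0: no locking at any K")
    x = (omega1 - omega2) / denom
    if abs(x) > 1.0:
        raise NoLockingError(
            f"|arcsin argument| = {abs(x):.3g} > 1: oscillators not locked")
    if K * c > 0:
        return float(np.arcsin(x)), "in_phase"
    return float(np.pi - np.arcsin(x)), "anti_phase"


def critical_coupling_two(omega1: float, omega2: float, tau: float,
                          Omega: float) -> tuple[float, bool]:
    """Critical coupling Kc = |omega_2 - omega_1| / |2 cos(Omega tau)|.

    Returns (Kc, diverged); ``diverged`` flags cos(Omega tau) = 0, where no
    locking exists at any coupling (Kc is inf there).
    """
    c = np.cos(Omega * tau)
    if abs(c) < 1e-12:
        return float("inf"), True
    return abs(omega2 - omega1) / abs(2.0 * c), False


def effective_params(omega: tuple[float, float], K: float, tau: float,
                     modulation: ModulationSpec, times: np.ndarray,
                     Omega: np.ndarray | float) -> EffectiveParams:
    """Time-varying effective coupling/frequencies and locking predictor.

    K_eff(t) = (K + eps_K sin w^_K t) cos(Omega(t) tau) and
    omega_eff_i(t) = omega_i + eps_i sin(w^_i t); the locking indicator is
    |2 K_eff| > |omega_eff_1 - omega_eff_2|.  With all amplitudes zero the
    series are constant.
    """
    times = np.asarray(times, dtype=float)
    Omega = np.broadcast_to(np.asarray(Omega, dtype=float), times.shape)
    Kt = K + modulation.eps_K * np.sin(modulation.omega_hat_K * times)
    K_eff = Kt * np.cos(Omega * tau)
    om_eff = np.empty((2, len(times)))
    for i in range(2):
        e = modulation.eps[i] if len(modulation.eps) > i else 0.0
        w = modulation.omega_hat[i] if len(modulation.omega_hat) > i else 0.0
        om_eff[i] = omega[i] + e * np.sin(w * times)
    dw_eff = om_eff[0] - om_eff[1]
    return EffectiveParams(times=times, K_eff=K_eff, omega_eff=om_eff,
                           delta_omega_eff=dw_eff,
                           locked_predictor=np.abs(2.0 * K_eff) > np.abs(dw_eff))
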