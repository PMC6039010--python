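"""Network specifications for delay-coupled Kuramoto oscillators.

The central object is :class:`OscillatorNetwork`: natural frequencies
``omega`` (rad/s), a symmetric coupling-weight matrix ``Kmat`` (applied with a
1/N prefactor by the integrator), a symmetric delay matrix ``taumat`` (s),
a noise intensity ``D``, and optional harmonic parameter modulation.  The
constructors cover every configuration studied by the phase-lag theory:
constant or Lorentzian natural frequencies, uniform or log-normal node
strengths, and single, bimodal-random, bimodal-clustered, or fully explicit
delay matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

TWO_PI = 2.0 * np.pi

__all__ = [
    "FrequencySpec",
    "StrengthSpec",
    "DelaySpec",
    "ModulationSpec",
    "OscillatorNetwork",
    "sample_lorentzian",
    "sample_lognormal_strengths",
    "build_network",
    "pair_network",
    "save_matrix",
    "load_matrix",
]


class SpecError(ValueError):
    """Raised for inconsistent or invalid model specifications."""


@dataclass(frozen=True)
class FrequencySpec:
    """Natural-frequency distribution.

    kind
        ``"constant"`` (all oscillators at ``mu``) or ``"lorentzian"``
        with density g(w) = gamma / pi / ((w - mu)^2 + gamma^2).
    mu
        Center frequency in rad/s.
    gamma
        Lorentzian half-width at half-maximum in rad/s (0 for constant).
    """

    kind: str = "constant"
    mu: float = TWO_PI
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "lorentzian"):
            raise SpecError(f"unknown frequency kind {self.kind!r}")
        if self.gamma < 0:
            raise SpecError("gamma must be >= 0")
        if self.mu <= 0:
            raise SpecError("mu must be > 0")

    @classmethod
    def from_hz(cls, kind: str, mu_hz: float, gamma: float = 0.0,
                gamma_in_hz: bool = False) -> "FrequencySpec":
        """Build a spec with the center given in Hz.

        A configuration like "mu = 1 Hz and gamma = 1" is ambiguous about
        the unit of gamma; by default gamma is taken in rad/s, set
        ``gamma_in_hz=True`` for the alternative reading.
        """
        g = gamma * TWO_PI if gamma_in_hz else gamma
        return cls(kind=kind, mu=mu_hz * TWO_PI, gamma=g)


@dataclass(frozen=True)
class StrengthSpec:
    """Node-strength (coupling) distribution.

    ``"uniform"`` uses the single value ``K`` for every link.  ``"lognormal"``
    draws per-node out-strengths with mean ``m`` and variance ``s``; the
    log-scale parameters follow the standard moment mapping
    mu_log = ln(m^2/sqrt(s + m^2)), sigma_log^2 = ln(1 + s/m^2).
    """

    kind: str = "uniform"
    K: float = 1.0
    m: float = 1.0
    s: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "lognormal"):
            raise SpecError(f"unknown strength kind {self.kind!r}")
        if self.kind == "uniform" and self.K < 0:
            raise SpecError("K must be >= 0")
        if self.kind == "lognormal":
            if self.m <= 0:
                raise SpecError("lognormal mean m must be > 0")
            if self.s < 0:
                raise SpecError("lognormal variance s must be >= 0")

    @property
    def mu_log(self) -> float:
        return float(np.log(self.m**2 / np.sqrt(self.s + self.m**2)))

    @property
    def sigma_log(self) -> float:
        return float(np.sqrt(np.log(1.0 + self.s / self.m**2)))


@dataclass(frozen=True)
class DelaySpec:
    """Delay architecture.

    kind
        ``"single"`` — every link at ``tau1``;
        ``"bimodal_random"`` — each link tau1 or tau2 with probability 1/2;
        ``"bimodal_clustered"`` — intra-cluster links tau1, inter-cluster tau2
        (two equal clusters);
        ``"matrix"`` — an explicit symmetric delay matrix.
    """

    kind: str = "single"
    tau1: float = 0.0
    tau2: float = 0.0
    matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("single", "bimodal_random", "bimodal_clustered",
                             "matrix"):
            raise SpecError(f"unknown delay kind {self.kind!r}")
        if self.tau1 < 0 or self.tau2 < 0:
            raise SpecError("delays must be >= 0")
        if self.kind.startswith("bimodal") and self.tau2 < self.tau1:
            raise SpecError("bimodal delays require tau1 <= tau2")
        if self.kind == "matrix":
            m = np.asarray(self.matrix, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise SpecError("delay matrix must be square")
            if np.any(m < 0):
                raise SpecError("delays must be >= 0")
            if not np.allclose(m, m.T):
                raise SpecError("delay matrix must be symmetric")
            if np.any(np.diag(m) != 0):
                raise SpecError("delay matrix diagonal must be zero")
            object.__setattr__(self, "matrix", m)

    @property
    def tau_mean(self) -> float:
        """Mean delay tau~ = (tau1 + tau2)/2."""
        return 0.5 * (self.tau1 + self.tau2)

    @property
    def tau_halfdiff(self) -> float:
        """Half-difference dtau = (tau2 - tau1)/2 >= 0."""
        return 0.5 * (self.tau2 - self.tau1)


@dataclass(frozen=True)
class ModulationSpec:
    """Harmonic modulation of natural frequencies and of the coupling.

    omega_i(t) = omega_i + eps_i sin(omega_hat_i t) and the coupling constant
    K -> K + eps_K sin(omega_hat_K t).  Zero amplitudes mean no modulation.
    """

    eps: tuple[float, ...] = ()
    omega_hat: tuple[float, ...] = ()
    eps_K: float = 0.0
    omega_hat_K: float = 0.0

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.eps) or self.eps_K < 0:
            raise SpecError("modulation amplitudes must be >= 0")
        if len(self.eps) != len(self.omega_hat):
            raise SpecError("eps and omega_hat must have equal length")

    @property
    def active(self) -> bool:
        return self.eps_K > 0 or any(e > 0 for e in self.eps)


@dataclass
class OscillatorNetwork:
    """A fully specified delay-coupled phase-oscillator network.

    Dynamics (integrated by :mod:`phaselag.simulate`):

        dtheta_i/dt = omega_i + (1/N) sum_j K_ij sin(theta_j(t - tau_ij)
                                                     - theta_i) + eta_i

    with Gaussian white noise of intensity ``D`` and optional harmonic
    modulation.  ``K_scale`` records the nominal global coupling constant
    (the K a configuration is quoted with) and drives the integration
    time-step rule.
    """

    N: int
    omega: np.ndarray
    Kmat: np.ndarray
    taumat: np.ndarray
    D: float = 0.0
    modulation: ModulationSpec = field(default_factory=ModulationSpec)
    cluster_label: np.ndarray | None = None
    K_scale: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.Kmat = np.asarray(self.Kmat, dtype=float)
        self.taumat = np.asarray(self.taumat, dtype=float)
        if self.omega.shape != (self.N,):
            raise SpecError("omega must have shape (N,)")
        for name, m in (("Kmat", self.Kmat), ("taumat", self.taumat)):
            if m.shape != (self.N, self.N):
                raise SpecError(f"{name} must have shape (N, N)")
            if not np.allclose(m, m.T):
                raise SpecError(f"{name} must be symmetric")
            if np.any(np.diag(m) != 0):
                raise SpecError(f"{name} diagonal must be zero")
        if np.any(self.Kmat < 0) or np.any(self.taumat < 0):
            raise SpecError("weights and delays must be >= 0")
        if self.D < 0:
            raise SpecError("noise intensity D must be >= 0")
        if self.cluster_label is not None:
            self.cluster_label = np.asarray(self.cluster_label, dtype=int)
            if self.cluster_label.shape != (self.N,):
                raise SpecError("cluster_label must have shape (N,)")
        if self.K_scale is None:
            self.K_scale = float(self.strengths.max()) if self.N else 0.0

    @property
    def strengths(self) -> np.ndarray:
        """Node strengths K_i = sum_j K_ij / N."""
        return self.Kmat.sum(axis=1) / self.N

    @property
    def max_delay(self) -> float:
        return float(self.taumat.max())

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "N": self.N,
            "omega": self.omega.tolist(),
            "Kmat": self.Kmat.tolist(),
            "taumat": self.taumat.tolist(),
            "D": self.D,
            "modulation": asdict(self.modulation),
            "cluster_label": (None if self.cluster_label is None
                              else self.cluster_label.tolist()),
            "K_scale": self.K_scale,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OscillatorNetwork":
        mod = d.get("modulation") or {}
        mod = ModulationSpec(eps=tuple(mod.get("eps", ())),
                             omega_hat=tuple(mod.get("omega_hat", ())),
                             eps_K=mod.get("eps_K", 0.0),
                             omega_hat_K=mod.get("omega_hat_K", 0.0))
        return cls(N=d["N"], omega=np.array(d["omega"]),
                   Kmat=np.array(d["Kmat"]), taumat=np.array(d["taumat"]),
                   D=d.get("D", 0.0), modulation=mod,
                   cluster_label=(None if d.get("cluster_label") is None
                                  else np.array(d["cluster_label"])),
                   K_scale=d.get("K_scale"), seed=d.get("seed"))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict()) if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict()))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "OscillatorNetwork":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


# -- samplers --------------------------------------------------------------

def sample_lorentzian(n: int, spec: FrequencySpec, seed: int) -> np.ndarray:
    """Draw ``n`` natural frequencies from the Lorentzian g(w)."""
    if n < 1:
        raise SpecError("n must be >= 1")
    if spec.kind != "lorentzian":
        raise SpecError("spec.kind must be 'lorentzian'")
    rng = np.random.default_rng(seed)
    # inverse-CDF: w = mu + gamma * tan(pi*(u - 1/2))
    u = rng.uniform(size=n)
    return spec.mu + spec.gamma * np.tan(np.pi * (u - 0.5))


def sample_lognormal_strengths(n: int, spec: StrengthSpec,
                               seed: int) -> np.ndarray:
    """Draw ``n`` per-node out-strengths from the log-normal strength law."""
    if spec.kind != "lognormal":
        raise SpecError("spec.kind must be 'lognormal'")
    if spec.m <= 0:
        raise SpecError("lognormal mean m must be > 0")
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=spec.mu_log, sigma=spec.sigma_log, size=n)


# -- network construction --------------------------------------------------

def _delay_matrix(N: int, delay: DelaySpec, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray | None]:
    labels = None
    if delay.kind == "matrix":
        if delay.matrix.shape != (N, N):
            raise SpecError("delay matrix size does not match N")
        return delay.matrix.copy(), None
    if delay.kind == "single":
        taumat = np.full((N, N), delay.tau1, dtype=float)
    elif delay.kind == "bimodal_random":
        iu = np.triu_indices(N, k=1)
        taumat = np.zeros((N, N))
        picks = rng.uniform(size=len(iu[0])) < 0.5
        vals = np.where(picks, delay.tau1, delay.tau2)
        taumat[iu] = vals
        taumat = taumat + taumat.T
    else:  # bimodal_clustered
        if N % 2:
            raise SpecError("bimodal_clustered layout requires even N")
        half = N // 2
        labels = np.r_[np.ones(half, int), np.full(half, 2, int)]
        taumat = np.full((N, N), delay.tau2, dtype=float)
        taumat[:half, :half] = delay.tau1
        taumat[half:, half:] = delay.tau1
    np.fill_diagonal(taumat, 0.0)
    return taumat, labels


def build_network(N: int, freq: FrequencySpec, strength: StrengthSpec,
                  delay: DelaySpec, D: float = 0.0,
                  modulation: ModulationSpec | None = None,
                  seed: int = 0) -> OscillatorNetwork:
    """Construct an :class:`OscillatorNetwork` from component specs.

    Log-normal strengths are assigned to each node's outgoing links and the
    weight matrix is then symmetrized as K_ij <- (K_ij + K_ji)/2, so the
    resulting in-strengths are approximately (not exactly) log-normal.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)

    if freq.kind == "constant":
        omega = np.full(N, freq.mu)
    else:
        omega = sample_lorentzian(N, freq, int(sub[0]))

    if strength.kind == "uniform":
        Kmat = np.full((N, N), strength.K, dtype=float)
        K_scale = strength.K
    else:
        Ki = sample_lognormal_strengths(N, strength, int(sub[1]))
        Kmat = np.tile(Ki[:, None], (1, N))   # out-strength on row i
        Kmat = 0.5 * (Kmat + Kmat.T)
        K_scale = strength.m     # nominal coupling of the configuration
    np.fill_diagonal(Kmat, 0.0)

    taumat, labels = _delay_matrix(N, delay, np.random.default_rng(int(sub[2])))

    return OscillatorNetwork(N=N, omega=omega, Kmat=Kmat, taumat=taumat,
                             D=D, modulation=modulation or ModulationSpec(),
                             cluster_label=labels, K_scale=K_scale, seed=seed)


def pair_network(omega1: float, omega2: float, K: float, tau: float,
                 D: float = 0.0,
                 modulation: ModulationSpec | None = None,
                 seed: int = 0) -> OscillatorNetwork:
    """Two delay-coupled oscillators with drive K sin(theta_other(t-tau) - theta_self).

    Because the network dynamics carry a 1/N prefactor, the stored weight is
    2K so that the integrated equations match the two-oscillator model with
    the quoted coupling constant K; ``K_scale`` records K itself.
    """
    Kmat = np.array([[0.0, 2.0 * K], [2.0 * K, 0.0]])
    taumat = np.array([[0.0, tau], [tau, 0.0]])
    return OscillatorNetwork(N=2, omega=np.array([omega1, omega2]),
                             Kmat=Kmat, taumat=taumat, D=D,
                             modulation=modulation or ModulationSpec(),
                             K_scale=K, seed=seed)


# -- delimited-text matrix I/O --------------------------------------------

def save_matrix(path: str | Path, M: np.ndarray) -> None:
    """Write a square matrix as header-free tab-separated text."""
    np.savetxt(path, np.asarray(M), delimiter="\t", fmt="%.12g")


def load_matrix(path: str | Path) -> np.ndarray:
    """Read a header-free delimited square matrix (tab or comma)."""
    text = Path(path).read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    M = np.loadtxt(path, delimiter=delim if delim in text else None)
    return np.atleast_2d(M)
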