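"""Connectome weight/length matrices: I/O, delays, and synthetic surrogates.

A connectome here is a pair of symmetric, zero-diagonal matrices — tract
weights W (counts or normalized) and tract lengths L (mm) — with a
hemisphere label per region.  Delays are lengths over a conduction
velocity (default 5 m/s).  The synthetic generator emulates the empirical
two-hemisphere structure: a bimodal tract-length distribution whose modes
correspond to intra- and inter-hemispheric links, log-normal weights, and
systematically weaker inter-hemispheric weights (tractography's negative
bias towards long interhemispheric tracts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .model import (DelaySpec, ModulationSpec, OscillatorNetwork,
                    load_matrix, save_matrix, TWO_PI)

__all__ = [
    "Connectome",
    "read_connectome",
    "write_connectome",
    "delays_from_lengths",
    "normalize_weights",
    "synth_connectome",
    "connectome_network",
]

DEFAULT_VELOCITY = 5.0     # m/s
MM_PER_M = 1000.0


class ConnectomeError(ValueError):
    pass


@dataclass
class Connectome:
    W: np.ndarray                      # weights, symmetric, zero diagonal
    L: np.ndarray                      # lengths (mm), symmetric, zero diag
    hemisphere: np.ndarray             # "left" | "right" per region
    labels: list[str] | None = None
    v: float = DEFAULT_VELOCITY        # conduction velocity, m/s

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        for name, m in (("W", self.W), ("L", self.L)):
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ConnectomeError(f"{name} must be square")
            if np.any(m < 0):
                raise ConnectomeError(f"{name} must be non-negative")
        if self.W.shape != self.L.shape:
            raise ConnectomeError("W and L sizes differ")
        self.hemisphere = np.asarray(self.hemisphere)
        if self.hemisphere.shape != (self.W.shape[0],):
            raise ConnectomeError("hemisphere labels must have length N")

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def taumat(self) -> np.ndarray:
        """Delay matrix tau_ij = L_ij / v (s), with L in mm."""
        return self.L / (MM_PER_M * self.v)

    @property
    def strengths(self) -> np.ndarray:
        """Node strengths K_i = sum_j W_ij / N."""
        return self.W.sum(axis=1) / self.N

    @property
    def intra_mask(self) -> np.ndarray:
        """Boolean off-diagonal mask of intra-hemispheric links."""
        same = self.hemisphere[:, None] == self.hemisphere[None, :]
        np.fill_diagonal(same, False)
        return same

    @property
    def inter_mask(self) -> np.ndarray:
        diff = self.hemisphere[:, None] != self.hemisphere[None, :]
        return diff


def _clean(name: str, M: np.ndarray, tol: float = 0.01) -> np.ndarray:
    """Symmetrize (if asymmetry <= tol, relative) and zero the diagonal."""
    asym = np.abs(M - M.T)
    scale = max(np.abs(M).max(), 1e-300)
    worst = np.unravel_index(np.argmax(asym), asym.shape)
    if asym.max() / scale > tol:
        i, j = int(worst[0]), int(worst[1])
        raise ConnectomeError(
            f"{name} asymmetric beyond {tol:.0%}: worst entry ({i}, {j}) "
            f"(|{M[i, j]:.6g} - {M[j, i]:.6g}|)")
    M = 0.5 * (M + M.T)
    if np.any(np.diag(M) != 0):
        warnings.warn(f"{name}: nonzero diagonal zeroed", UserWarning,
                      stacklevel=3)
        np.fill_diagonal(M, 0.0)
    np.fill_diagonal(M, 0.0)
    return M


def read_connectome(weights_path: str | Path, lengths_path: str | Path,
                    labels: list[str] | str | Path | None = None,
                    v: float = DEFAULT_VELOCITY) -> Connectome:
    """Read weight and length matrices from header-free delimited text.

    Matrices are symmetrized by averaging with their transpose when the
    relative asymmetry is at most 1% (an error names the worst entry
    otherwise) and the diagonal is zeroed.  Hemisphere assignment follows
    the usual atlas ordering (first half left) unless a one-column label
    file/list with entries containing "left"/"right" (or "lh"/"rh") is
    given.
    """
    W = _clean("weights", load_matrix(weights_path))
    L = _clean("lengths", load_matrix(lengths_path))
    if W.shape != L.shape:
        raise ConnectomeError(
            f"size mismatch: weights {W.shape} vs lengths {L.shape}")
    N = W.shape[0]
    names = None
    if labels is None:
        hemi = np.array(["left"] * (N // 2) + ["right"] * (N - N // 2))
    else:
        if isinstance(labels, (str, Path)):
            names = Path(labels).read_text().split()
        else:
            names = list(labels)
        if len(names) != N:
            raise ConnectomeError("label count does not match matrix size")
        hemi = np.array(["left" if ("left" in s.lower() or
                                    s.lower().startswith("lh"))
                         else "right" for s in names])
    return Connectome(W=W, L=L, hemisphere=hemi, labels=names, v=v)


def write_connectome(con: Connectome, weights_path: str | Path,
                     lengths_path: str | Path) -> None:
    save_matrix(weights_path, con.W)
    save_matrix(lengths_path, con.L)


def delays_from_lengths(con: Connectome,
                        v: float | None = None) -> np.ndarray:
    """Delay matrix tau_ij = L_ij / v with mm -> m conversion."""
    v = con.v if v is None else v
    if v <= 0:
        raise ConnectomeError("conduction velocity must be > 0")
    return con.L / (MM_PER_M * v)


def normalize_weights(con: Connectome, mode: str = "max") -> Connectome:
    """Rescale the weight matrix.

    ``"max"`` (default) divides by the largest entry; ``"mean_strength"``
    scales so the mean node strength K_i is 1.  The global coupling K is
    applied at simulation time on top of the normalized weights.
    """
    if con.W.max() == 0:
        raise ConnectomeError("all-zero weight matrix")
    if mode == "max":
        scale = con.W.max()
    elif mode == "mean_strength":
        scale = con.strengths.mean()
    else:
        raise ConnectomeError(f"unknown normalization mode {mode!r}")
    return replace(con, W=con.W / scale)


def synth_connectome(N: int = 68, intra_length_mode: float = 50.0,
                     inter_length_mode: float = 130.0,
                     length_spread: float = 15.0,
                     weight_mean: float = 1.0,
                     weight_var: float = 1.0,
                     inter_weight_factor: float = 0.3,
                     seed: int = 0) -> Connectome:
    """Synthetic two-hemisphere connectome with bimodal tract lengths.

    Intra-hemispheric lengths are drawn around ``intra_length_mode`` and
    inter-hemispheric around ``inter_length_mode`` (mm, truncated positive
    normal with SD ``length_spread``); weights are log-normal with the
    given mean/variance, and inter-hemispheric weights are multiplied by
    ``inter_weight_factor`` < 1.  Matrices are symmetric with zero
    diagonal; hemispheres are the first and second half of the nodes.
    """
    if N % 2:
        raise ConnectomeError("N must be even")
    if inter_length_mode <= intra_length_mode:
        raise ConnectomeError("inter mode must exceed intra mode")
    rng = np.random.default_rng(seed)
    half = N // 2
    hemi = np.array(["left"] * half + ["right"] * half)

    L = np.zeros((N, N))
    W = np.zeros((N, N))
    mu_log = np.log(weight_mean**2 / np.sqrt(weight_var + weight_mean**2))
    sig_log = np.sqrt(np.log(1.0 + weight_var / weight_mean**2))
    iu = np.triu_indices(N, k=1)
    same = hemi[iu[0]] == hemi[iu[1]]
    modes = np.where(same, intra_length_mode, inter_length_mode)
    lengths = rng.normal(modes, length_spread)
    lengths = np.abs(lengths) + 1e-6           # reflect at zero
    weights = rng.lognormal(mu_log, sig_log, size=len(iu[0]))
    weights = np.where(same, weights, weights * inter_weight_factor)
    L[iu] = lengths
    W[iu] = weights
    L = L + L.T
    W = W + W.T
    return Connectome(W=W, L=L, hemisphere=hemi, v=DEFAULT_VELOCITY)


def connectome_network(con: Connectome, K: float, f_hz: float, D: float,
                       normalization: str | None = "max",
                       v: float | None = None) -> OscillatorNetwork:
    """Oscillator network over a connectome.

    The global coupling ``K`` multiplies the normalized weights and each
    oscillator sums its weighted inputs, so the effective per-link coupling
    is K * w_ij and node strengths are K * sum_j w_ij — the inhomogeneous
    strengths the phase-lag theory operates on.  All natural frequencies
    are 2 pi f (identical oscillators with stochastic inhomogeneity);
    delays come from tract lengths at velocity ``v``; hemispheres become
    the cluster labels.
    """
    c = normalize_weights(con, normalization) if normalization else con
    taumat = delays_from_lengths(c, v)
    Kmat = K * c.W * c.N       # simulator applies 1/N: drive K sum_j w_ij
    labels = np.where(c.hemisphere == "left", 1, 2)
    omega = np.full(c.N, f_hz * TWO_PI)
    K_scale = float(K * c.W.sum(axis=1).max())
    return OscillatorNetwork(N=c.N, omega=omega, Kmat=Kmat, taumat=taumat,
                             D=D, modulation=ModulationSpec(),
                             cluster_label=labels, K_scale=K_scale)
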