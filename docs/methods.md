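# Methods

## Model

The package studies phase lags in networks of delay-coupled Kuramoto
oscillators,

    dθ_i/dt = ω_i + (1/N) Σ_j K_ij sin(θ_j(t − τ_ij) − θ_i) + η_i(t),

with symmetric weights K_ij and delays τ_ij, and Gaussian white noise
⟨η_i(t) η_j(t′)⟩ = 2D δ(t−t′) δ_ij.  Natural frequencies are either
constant or Lorentzian, g(ω) = γ/π/[(ω−μ)² + γ²].  For the two-oscillator
system the convention is the non-averaged form
dθ_{1,2}/dt = ω_{1,2} − K sin(θ_{1,2} − θ_{2,1}(t−τ)); `pair_network()`
stores K_ij = 2K so that the N-averaged network equation reproduces it
with the quoted K.  Optionally, ω_i and K are modulated harmonically
(ε sin ω̂t) to emulate non-autonomous dynamics.

Frequencies are handled in rad/s throughout.  Parameters
given in Hz are converted with ω = 2πf; a Lorentzian scale "γ = 1" is
taken in rad/s (the Hz reading is available through
`FrequencySpec.from_hz(..., gamma_in_hz=True)`).

## Integration scheme

A Heun (predictor–corrector) scheme adapted to delays: each distinct delay
is rounded to the nearest integer multiple of the step dt (exact for the
bimodal-δ architectures; error ≤ dt/2 otherwise) and past phases are kept
in a ring buffer.  The same Gaussian increment of variance 2D·dt enters
predictor and corrector (standard additive-noise Heun).  The corrector
reads delayed states at t+dt from history; zero-delay links read the
predictor state.  For noise-free runs the scheme converges at second
order (verified on commensurate-delay pairs).

The step is dt = 0.01 / max(K, 0.05μ, D, 1) with K the nominal global
coupling — the uniform coupling value, the log-normal mean strength, or
the maximum connectome node strength (`OscillatorNetwork.K_scale`) —
so dt never exceeds 0.01 s and shrinks for strong coupling, fast
oscillators, or strong noise.  History for t ≤ 0 is the free rotation
θ_i(0) + ω_i t; initial phases are uniform on [−π, π) unless given.
Output is decimated to 4× the fastest natural frequency (a "twice the
Nyquist rate" convention; the factor is configurable in `downsample`),
capped at the raw rate for heavy-tailed frequency draws.  A sensible
warm-up to discard is max(10 periods of μ, 2·max delay)
(`default_warmup`); tests and examples state theirs explicitly.

Two coupling-evaluation paths give identical results: a dense mean-field
path (one BLAS mat-vec per distinct delay — used for the bimodal
architectures) and a per-link gather path (used for connectome-like
matrices with many distinct delays).

## Two-oscillator theory

Locked states satisfy Ω = (ω₁+ω₂)/2 − K sin(Ωτ) cos φ with
sin φ = (ω₁−ω₂)/(2K cos Ωτ).  Both arcsine branches are scanned on
[mean−K, mean+K] (2000-point grid, bisection to 1e-10); a root is stable
iff K cos(Ωτ) cos(φ) > 0, in-phase iff φ ∈ (−π/2, π/2) (equivalently
K cos Ωτ > 0 for stable roots), and the critical coupling is
Kc = |ω₂−ω₁|/|2 cos Ωτ| (divergent where cos Ωτ = 0: no locking at any
coupling).  Multistable root sets are returned in full; which root a
noisy simulation selects is an initial-condition/noise question the
theory deliberately leaves open.  For non-autonomous parameters the
effective quantities K_eff(t) = (K + ε_K sin ω̂_K t) cos(Ω(t)τ) and
ω_eff,i(t) = ω_i + ε_i sin(ω̂_i t) yield the locking indicator
|2K_eff| > |Δω_eff|.

## Network mean-field theory

For all-to-all networks with bimodal-δ delays (equal peaks at τ₁, τ₂),
with τ̃ = (τ₁+τ₂)/2 and Δτ = (τ₂−τ₁)/2, steady partial synchronization at
(Ω, r) obeys

- random delays / clustered in-phase: Ω = μ − (K/2)(r²+1) sin(Ωτ̃) cos(ΩΔτ)
- clustered anti-phase (Ωτ₂ in the left half-plane):
  Ω = μ + (K/2)(r²+1) cos(Ωτ̃) sin(ΩΔτ)

and entrained relative phases follow φ_i + Ωτ̃ = arcsin((ω_i−Ω)/(K_i r
cos ΩΔτ)) (in-phase) or arccos(−(ω_i−Ω)/(K_i r sin ΩΔτ)) (anti-phase),
with branch intervals set by the half-plane of ΩΔτ and entrainment
conditions K_i r |cos ΩΔτ| > |ω_i−Ω| resp. K_i r |sin ΩΔτ| > |ω_i−Ω|.
For identical oscillators with noise the stochastic heterogeneity
averages out and μ replaces ω_i.  The two-cluster offset is ψ₂ = 0 for
Ωτ₂ in the right complex half-plane and π otherwise.  Because the
coupling sum sin(φ+Ωτ₁) + sin(φ+Ωτ₂) = 2 sin(φ+Ωτ̃) cos(ΩΔτ) is
invariant under a joint π-shift of (Ωτ̃, ΩΔτ), all predictions are
evaluated with Ωτ̃ normalized to the right half-plane
(`normalize_angles`); quadrant boundaries are assigned to the lower
quadrant and flagged marginal.

The coherence is closed through the Ott–Antonsen reduction (exact for
Lorentzian frequencies): the delay-coupled order-parameter ODE
ż = (iμ−γ)z − (K/4)[(z²z*_{t−τ₁} − z_{t−τ₁}) + (z²z*_{t−τ₂} − z_{t−τ₂})]
(random; the coupled z^I/z^II pair for clusters) has fixed points whose
real part gives r² = 1 − 2γ/(K cos Ωτ̃ cos ΩΔτ) (in-phase) and
r² = 1 − 2γ/(K sin Ωτ̃ sin ΩΔτ) (anti-phase).  `sync_frequency_network`
co-solves (Ω, r) by substituting these into the Ω equation when r is not
supplied; supplying a measured r instead is the recommended route for
comparing against simulations.  Root stability is labeled by the slope
criterion F′(Ω) < 0 of the self-consistency residual — a cheap proxy
whose agreement with converged OA integration is exercised in the test
suite rather than recomputed per root.  The OA ODE is integrated with
the same delay-Heun machinery (complex state, deterministic); for noisy
identical oscillators D plays the role of γ.

Trend tables map the quadrants of (Ωτ₁, Ωτ₂) to the direction in which
entrained phases move as node strength grows; cells with two listed
directions return both labels, and the caller reports per branch.  The
single-sign summary is geometric: with Ωτ̃ (after normalization) in the
first quadrant the frequency is depressed (Ω < μ) and stronger nodes
lag; in the fourth quadrant Ω > μ and stronger nodes lead.

## PLV statistics

cPLV = (1/M) Σ_p e^{i(θ_a−θ_b)} on sliding windows of 10 periods of the
mean entrainment frequency (read as the measured mean-field rotation
rate; configurable) with 75% overlap; windows shorter than 10 samples
are rejected.  Significance is the 95th percentile of the per-surrogate
maximum windowed PLV over 100 surrogates.  Two surrogate constructions:
(a) shuffle — random permutation of one series' wrapped phase samples,
computed for a designated pair and applied globally (the laxer level);
(b) uncoupled — per-pair zero-coupling twins with the same frequencies
and noise.  Because the K=0 phase SDE integrates in closed form
(θ₀ + ωt + √(2D)W(t)), uncoupled surrogates are sampled exactly on the
output grid rather than integrated numerically.  Circular mean is the
resultant argument; circular SD is √(−2 ln R̄); lag histograms use 50
bins on [−π, π].  Cluster regimes are labeled anti-phase where the
hemispheric mean-field distance exceeds π/2 (exactly π/2 counts as
in-phase), and are undefined when either cluster coherence drops below a
floor (default 0.1).

## Synthetic connectomes

The generator emulates the gross two-hemisphere structure of a
68-region tractography connectome: intra-hemispheric tract lengths
around 50 mm and inter-hemispheric around 130 mm (truncated normal,
SD 15 mm) — giving the bimodal delay distribution at 5 m/s that motivates
the clustered-delay theory — log-normal weights (mean 1, variance 1),
and inter-hemispheric weights suppressed by a factor 0.3 (tractography's
negative bias toward long inter-hemispheric tracts).  It does not
emulate spatial embedding, distance-dependent weight decay, homotopic
connections, or realistic degree distributions, so connectome-level
results here demonstrate the mechanism (delay-organized in-/anti-phase
clustering and strength-ordered lags), not region-level predictions for
real anatomy.

`connectome_network` normalizes weights by the matrix maximum and uses
the summed-input convention — effective per-link coupling K·w_ij, node
strength K·Σ_j w_ij — under which global couplings of order 1 with noise
D of order 1 produce the partially coherent regimes of interest; under
the strictly N-averaged convention the same values leave the network
deeply subcritical.  Mean-strength normalization (mean K_i = 1) is
available as an alternative mode.

## Numerical choices and scaled problem sizes

- Root scans: 2000 points (pair) / 4000 points (network) with bisection
  to 1e-10; duplicate roots within 1e-6 rad/s are merged.
- OA steadiness: converged when |z| varies by < 1e-4 (relative) over the
  final 10% of the run; the rotation rate is a linear fit to the
  unwrapped phase over that span.
- Delay rounding: nearest integer multiple of dt; the convergence test
  uses commensurate delays so the O(dt) rounding error does not mask the
  scheme's O(dt²) accuracy.
- The anti-phase cluster state is multistable with the in-phase state;
  runs meant to characterize it are prepared with one cluster's initial
  phases offset by π (basin selection, not a parameter change).
- Test problem sizes: headline pair runs use the full 100 s; the
  clustered anti-phase check uses N=300 for 200 s; theory-vs-simulation
  agreement uses N=300 for 200 s; trend-sign recovery uses N=150 for
  120 s per quadrant case; OA-vs-simulation uses N=300, 150 s, averaged
  over seeds that reach steady partial synchronization (the reduction's
  validity regime — strongly fluctuating, standing-wave-like runs are
  excluded by a σ_r < 0.1·r̄ criterion); connectome scenarios use N=68
  for 120 s.  These sizes are the package's defaults for its validation
  suite; all scale up by passing larger `t_final`/`N`.

## Known limitations

- The mean-field theory assumes steady partial synchronization; standing
  waves, breathing states, and multistability beyond the two delay-
  imposed branches are outside its scope (the simulator still produces
  them).
- The per-node coupling approximation (K_i = row-average strength)
  ignores weight-topology correlations; heavy-tailed connectomes weaken
  the node-level phase predictions even when the regime-level picture
  holds.
- Delay modulation, asymmetric couplings, and n:m locking are not
  modeled; the PLV pipeline is 1:1 only.
- Shuffle surrogates destroy all temporal structure, so their level is
  lax for strongly autocorrelated phases; the uncoupled level requires
  knowing (or estimating) the generative parameters.
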