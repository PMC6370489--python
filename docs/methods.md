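# Methods

## Models

Both brain network models couple 66 neural masses through a symmetric,
non-negative structural weight matrix `C` with zero diagonal and unit
spectral norm, and per-pair conduction delays `τ_np` (fiber length /
5.45 m/s, mean 11 ms over connected pairs). Integration is explicit
Euler at dt = 0.1 ms by default (0.2 ms in the large acceptance runs);
delayed states are read from a ring buffer with delays rounded to the
nearest step (≤ 0.5 % rounding error at the default dt), and the
history before t = 0 is frozen at the initial state. The first 20 s of
every run are discarded as transient.

**Firing rate.** `τ₀ ṙ_n = −r_n + (k/c₁) Σ_p C_np r_p(t−τ_np) + σ n(t)`
with τ₀ = 20 ms, σ = 2 and k ∈ {0.3, 0.9, 0.999}. The coupling is
normalized by the leading eigenvalue c₁ of C, so the noise-free system
is linearly stable exactly when k < 1; the stationary fluctuations are
entirely noise-driven, with mode variances ∝ 1/(1 − k λᵢ/c₁). Noise is
Euler–Maruyama: σ·√dt·N(0,1) per node per step. Initial rates are
Uniform(0, 1).

**Kuramoto.** `θ̇_n = ω_n + k Σ_p C_np sin(θ_p(t−τ_np) − θ_n)` with
ω_n ~ Normal(60, 2) rad/s drawn once per run, k ∈ {3, 13, 60}, initial
phases Uniform(0, 2π), and the observable sin θ_n driving the
hemodynamics. Two numerical readings deserve comment because the
literature is genuinely ambiguous about them:

- *Frequency units.* The nominal frequency parameters enter the phase
  equation directly as rad/s. Converting them by 2π would put the
  frequency dispersion (≈ 12.6 rad/s) above what k = 13 can synchronize
  for a unit-spectral-norm C (critical coupling ≈ 20), leaving the
  model incoherent at every preset. As implemented, k = 3 / 13 / 60
  produce the incoherent, partially synchronized (module-level
  clusters, global order parameter R ≈ 0.4 ± 0.17) and fully
  synchronized (R ≈ 0.92) regimes, with delay phase lags ω·τ ≈ 0.66 rad.
- *Noise.* The Kuramoto model is run deterministically (σ = 0, but
  configurable). Its BOLD-band signal rides on slow beats between
  partially locked phase clusters, a component that is orders of
  magnitude weaker than the rectified broadband floor introduced by
  even small white phase noise; with any appreciable σ the model's
  spatial structure disappears entirely from the BOLD (within-module FC
  drops from ≈ 0.7 to ≈ 0.0). The firing-rate model, whose output *is*
  its noise response, keeps σ = 2.

## Hemodynamics

Each ROI independently passes through the 4-state Balloon-Windkessel
system (vasodilatory signal, inflow, venous volume, deoxyhemoglobin)
with the canonical rate constants κ = 0.65 s⁻¹, γ = 0.41 s⁻¹,
τ = 0.98 s, α = 0.32, E₀ = 0.34, V₀ = 0.02, k₁ = 7E₀, k₂ = 2,
k₃ = 2E₀ − 0.2, integrated with Euler at the neural dt; the resting
state maps to zero output, and a 1 s box input peaks ≈ 3.4 s after
onset. An integration failure (flow ≤ 0) raises a diagnostic rather
than silently continuing. Because the firing-rate amplitude diverges as
k → 1 and its absolute scale is arbitrary, the pipeline standardizes
the firing-rate drive to peak amplitude 0.25 before the balloon (the
Kuramoto observable is already bounded); a sustained drive beyond about
−0.3 would push the flow out of its physical range.

Downsampling to TR = 0.72 s takes every round(TR/dt)-th sample; an
optional zero-phase low-pass guard at the TR Nyquist is available but
off in the analysis pipeline — the balloon itself attenuates power
above the band so strongly that the guard changes the band-limited
spectrum by less than measurement noise (verified: identical fitted
slopes with and without).

### Spectral slope note

The fitted (1/f)ⁿ exponent of unpreprocessed simulated BOLD over
0.01–0.25 Hz is ≈ 1.85 for both models. Because the in-band neural
spectrum of both models is essentially flat, this exponent equals the
log-log slope of the hemodynamic transfer power |H(f)|², which is fixed
by the balloon constants: the rate-constant set used here gives 1.95
analytically; reading 0.65/0.41 as time constants instead gives 0.43,
and other published sets give 0.26–2.7. No published constant set
yields both a physiological HRF peak (3–8 s) and exponents near 0.7;
reported sub-unity exponents for this class of simulation are therefore
not reproducible from the model equations alone, and the package keeps
the constants with the physiological impulse response.

## Preprocessing

One shared path for every dataset: per-ROI z-score (population SD) →
zero-phase 5th-order Butterworth band-pass 0.01–0.25 Hz → global signal
regression (OLS of each ROI on the unweighted across-ROI mean, with
intercept) → final z-score. Provenance flags record the applied steps.

## Synthetic connectome

The generator emulates the gross statistics of a 66-ROI
tractography-derived cortical connectome. ROI centroids sit on two
mirrored rings; each hemisphere holds four contiguous subnetwork
modules, mirrored across the midline, and the modules pair into two
weakly coupled super-groups — a task-positive/task-negative-like
bipartition, which is the dominant functional axis of the cortex.
Connection densities are 0.9 within a module, 0.5 between modules of a
hemisphere and 0.3 across the midline (density ≈ 0.46 overall, matching
coarse-parcellation tractography); weights are log-normal (σ = 0.5)
with exponential distance decay, ×30 within modules, ×6 on homotopic
pairs, ×0.3 across super-groups, and ×4 interhemispheric before the
final unit-spectral-norm normalization. Fiber lengths are
centroid-distance × tortuosity, rescaled once so the mean connected-pair
delay is exactly 11 ms at 5.45 m/s.

These choices were fixed by matching structural statistics of real
connectomes — heavy-tailed weights, strong community structure
(near-degenerate leading eigenmodes λ₂–λ₅ ≈ 0.79–0.92 of λ₁), row sums
close to the spectral norm — and produce post-GSR FC spread (sd ≈ 0.3)
in the empirically reported range. A near-uniform or very sparse
matrix fails on both counts: its FC spread is so small that
event-counting metrics drown in sampling noise, and its row-sum deficit
suppresses Kuramoto synchronization.

## Surrogate resting state

The surrogate scan generator emulates the statistical features the
analysis metrics are sensitive to: a hidden Markov chain over a few
covariance regimes (default 3 states, mean dwell 60 TRs) driving
correlated Gaussian innovations; 1/f^0.9 spectral shaping (the
empirically reported unfiltered exponent); and a 28-TR traveling motif
(Gaussian bumps staggered in a random ROI order, random signs) inserted
every 1.5 motif lengths — a 20 s pattern twice per minute, the reported
occurrence rate. It deliberately omits hemodynamic nonlinearity, head
motion, physiological noise and scanner artifacts, so passing tests
demonstrate correct metric behavior on controlled dynamics, not
performance on real data.

## Analysis choices

- **Coactivation:** events are upward threshold crossings (the sample
  before the scan counts as below threshold); entry (i,j) is the
  fraction of i's crossings with a j crossing within ±3 TRs; rows of
  ROIs without crossings are reported missing, not zero; the matrix is
  symmetrized as (M+Mᵀ)/2 for FC comparison; thresholds 0 and 1 are
  both available, 1 being the headline.
- **Spectral slope:** Welch per ROI (nperseg = 256), ROI-averaged,
  least-squares line on log power vs log frequency in 0.01–0.25 Hz;
  returns the negated slope.
- **QPP:** window = round(20 s / TR) = 28 TRs; sliding correlations via
  a precomputed normalized window matrix; peaks above 0.1 (first two
  iterations) then 0.2, minimum separation window/2; convergence at
  successive-template correlation > 0.9999; 10 random starts. The
  winning start maximizes the *mean* supra-threshold peak correlation
  (with a ≥ 3-peak guard): a sum-based score provably favours
  phase-rolled templates that split each occurrence into two weaker
  peaks. Degenerate (no-peak) starts yield an unconverged result, never
  an error.
- **States:** 60-TR windows stepped by 1; correlations clipped at
  1 − 10⁻⁶ before Fisher z; k-means with L1 assignment and
  componentwise-median updates, best of 30 seeded restarts by total
  within-cluster L1 distance; empty clusters re-seeded at the worst-fit
  point. Dwell times in seconds (windows × TR). Transition matrices
  pool label changes across runs, normalize by total changes, zero the
  diagonal; sparsity is the occupied fraction of k(k−1) cells.
- **RQA:** recurrence = Pearson correlation of spatial patterns ≥ 0.3;
  RR sums all N² cells including the main diagonal; diagonal-line
  statistics exclude the line of identity, count each symmetric pair
  once, use l_min = 2, and normalize P(l) before the entropy
  (−Σ p ln p, nats).

## Problem sizes

The default test suite runs simulations of 120–620 s at dt 0.2–1 ms;
the acceptance script uses the full protocol resolution (600 s analyzed
per run at dt = 0.2 ms, 3 seeds per model). The full-study preset
(30 × 15 min runs at dt = 0.1 ms) is available through
`ExperimentConfig.from_preset("study")`.

## Known limitations

- The Kuramoto model's slow BOLD structure on the synthetic connectome
  is beat-driven and seed-sensitive: which partition beats, and how
  fast, depends on the drawn natural frequencies. Cross-model QPP
  template agreement is correspondingly weak here (≈ 0.1), although
  each model's own template is stable and the firing-rate template
  matches the described phenomenology (dominant bipartition oscillating
  at the ≈ 12 s hemodynamic resonance).
- Fitted spectral exponents reflect the hemodynamic constants, not the
  network (see the spectral slope note).
- Homogeneous node parameters and hemodynamics; no subcortex; no
  directionality in the connectome.
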