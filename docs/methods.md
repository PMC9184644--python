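# Methods

## Model

The dynamical core is the delayed Kuramoto network

θ̇ᵢ = ωᵢ + (K/N) Σⱼ cᵢⱼ sin(θⱼ(t − τᵢⱼ) − θᵢ) + d ζᵢ(t),

with two instantiations:

- **All-to-all** (`kuramoto.simulate_uniform`): cᵢⱼ ≡ 1, one uniform
  delay τ, natural frequencies drawn from a Lorentzian with center μ and
  half-width γ. This is the analytically tractable tier: for N → ∞ the
  Ott–Antonsen ansatz closes the dynamics of the order parameter
  z = (1/N) Σ e^{iθᵢ} into ż = (iμ − γ)z − (K/2)(z²z̄_{t−τ} − z_{t−τ}),
  and rotating-wave steady states give the transcendental system solved
  in `oa_theory` (plus its third-order Taylor-cubic approximation).
- **Connectome-coupled** (`kuramoto.simulate_network`): weights cᵢⱼ from
  a structural connectome, per-pair delays τᵢⱼ = Dᵢⱼ/v, and natural
  frequencies assigned from node strength: the weakest node oscillates at
  ω_max = 12 Hz, the strongest hub at ω_min = 8 Hz, interpolating
  quadratically in normalized strength. On realistic connectomes this
  yields a mean natural frequency near 11 Hz.

### Unit convention

All user-facing frequency-like quantities — μ, γ, Ω, ωᵢ **and the
coupling K** — are in Hz and converted to rad/s internally (×2π). This
keeps ratios like K/γ meaningful across the simulator and the analytical
layer (the critical coupling at τ = 0 is K = 2γ in any consistent
units). The noise amplitude `d` multiplies √dt · N(0, 1) per oscillator
per step and is applied as given, without 2π conversion; the whole-brain
sweep default is d = 3.

### Numerical integration

Euler–Maruyama with dt = 1 ms, 30 s runs, first 10 s discarded
(defaults; all overridable). Delays are rounded to the nearest integer
multiple of dt and served from a ring buffer; history is constant at the
initial phases for t < 0, an arbitrary choice whose startup transient the
discarded 10 s absorbs. The all-to-all integrator uses the exact identity
Σⱼ sin(θⱼ(t−τ) − θᵢ) = N·r(t−τ)·sin(φ(t−τ) − θᵢ) to run in O(N) per
step, which is what makes the N = 1000 tier desk-scale; both inner loops
are numba-compiled. Doubling dt to 2 ms changes locked-state r by < 0.02
(guarded by a test).

The reduced delay ODE is integrated by explicit Euler at dt = 10 µs. The
explicit step inflates |z| by ≈ μ²dt/2 per unit time (the chord of the
fast rotation); at the default step this bias in r is ~1e-3 and is the
reason the default is finer than the network integrator's.

### Summary statistics

- Order parameter r(t), metastability = population SD of r(t) after the
  transient.
- **Mean network frequency** (used on connectome sweeps): mean over
  oscillators of the unwrapped-phase slope.
- **Locked-cluster frequency** (used for the all-to-all/theory
  comparisons): mean of per-oscillator frequencies within 0.5 Hz of the
  population median. The Lorentzian's heavy tails leave a minority of
  drifting oscillators whose extreme natural frequencies would otherwise
  dominate a plain mean; the median-anchored cluster is what "the
  synchronization frequency" refers to analytically. On the connectome
  model the frequency support is the bounded 8–12 Hz band and the plain
  mean is used.
- Model PLV: |time-mean e^{i(θᵢ−θⱼ)}| over post-transient samples,
  averaged over distinct pairs.

### Steady-state branch solving

`solve_transcendental` scans F(Ω) = μ − K sin Ωτ + γ tan Ωτ − Ω on a
0.01 Hz grid over Ω ∈ (0, 2μ] by default (excluding tangent poles and
brackets that straddle them), polishes sign changes with Brent's method
to |F| < 1e-10, annotates each root with r₀ and the existence condition
cos Ωτ ≥ 2γ/K, and returns existing branches sorted by r₀. The
**dominant branch** is the largest-r₀ one — a conventional stability
proxy, used wherever a single (Ω, r₀) must be compared to simulation. In
multistable regions (Ωτ spanning > π) the simulation's branch selection
depends on initial conditions; the agreement tests run at delays where
the dominant branch is the attracting one. For the Taylor cubic, both
the exact existence condition and its approximation Ω²τ² ≤ 2 − 4γ/K are
evaluated; the exact one is authoritative.

## Spectral model and PAF

Welch spectra (5 s Hann windows, 50 % overlap; per-epoch averaging for
epoched input) are fitted in the 2–20 Hz range with the semi-log model
log P = b − χ log F + Σₘ aₘ exp(−(F − cₘ)²/2wₘ²), m ≤ 3: a robust
aperiodic line fit that ignores the top residual quartile (peaks only
push residuals up), iterative Gaussian extraction from the flattened
spectrum with a 2-SD relative threshold (plus a 0.1 log-power absolute
floor), then joint least-squares refinement. Natural logarithms are used
throughout; the base only shifts b. The aperiodic form is the
two-parameter (no-knee) one, adequate over 2–20 Hz. PAF is the center of
the largest-amplitude peak with 6 Hz ≤ c ≤ 14 Hz — the span of the lower
and upper alpha bands — and per-subject PAF is the arithmetic mean over
regions with such a peak.

## Phase locking

Per 5 s epoch: 4th-order Butterworth band-pass applied forward-backward
(zero-phase, so no filter-induced lag bias in Δφ), Hilbert phase, 10 % of
samples discarded at each epoch edge against boundary distortion. Phase
differences are wrapped to (−π, π] before the PLI sign (unwrapped
differences would make the sign meaningless). PLV/PLI are computed per
epoch, averaged across epochs, then across distinct pairs. Note that
band-limiting reduces the effective number of independent phase samples
to roughly 2 × bandwidth × epoch length, so the null PLV floor of a 4 Hz
band on 5 s epochs is ≈ 0.16, not 1/√T.

Surrogates permute the epoch pairing between channels (channel 0 as
reference), recomputing the epoch-averaged statistic 100 times by
default; p-values use the add-one permutation rule and cannot be zero.
Age trends are Pearson correlations with two-tailed t-based p-values; a
bootstrap-style subject subsample is available as an option.

## Synthetic data

The generator produces the study conditions every downstream stage is
tested against, with known ground truth:

- **Cohort** (`make_cohort`): ages uniform on 18–88 years; true PAF =
  intercept (10.5 Hz at the youngest age) + slope (−0.03 Hz/year) ×
  (age − 18) + N(0, 0.4 Hz), resampled if outside (4, fs/2 − 4) Hz.
  Signals at fs = 100 Hz in 5 s epochs: a constant-amplitude cosine of a
  Brownian-diffusing phase at the subject's PAF (diffusion 2π rad²/s,
  i.e. ~1 Hz FWHM — real subjects' peak width is unreported, this is a
  package choice) on top of FFT-shaped Gaussian noise with power-law PSD
  f^(−χ), χ uniform on 0.8–1.2 per subject. Channels share the alpha
  phase up to a per-channel index × lag (default π/4) plus
  (1 − coupling) × independent per-sample uniform phase noise, default
  coupling 0.8 — so subject-specific-band locking is age-invariant by
  construction while PAF declines. Because the 1/f background is higher at
  lower frequencies, the alpha amplitude is scaled per subject so the
  peak-to-background ratio at the subject's PAF equals that of a 10 Hz
  subject; otherwise band SNR — and with it measured phase locking —
  would covary with age through the amplitude, not the coupling. Default 8 channels × 24 epochs
  (2 min of data per subject; the pipeline scales linearly if the full
  8 min ≈ 96 epochs are wanted).
- **Coupled signals** (`make_coupled_signals`): the same shared-phase
  mixing without the aperiodic background, for estimator calibration.
  The independent phase noise is i.i.d. uniform per sample so that at
  coupling = 0 the pairwise PLV follows the exact null resultant-length
  distribution.
- **Connectome** (`make_synthetic_connectome`): coordinates uniform in a
  140 mm-radius sphere (inter-node distances ~tens of mm, matching
  cortical parcellations), weights exp(−D/80 mm) with log-normal noise,
  optional density thinning, max-normalized. Disconnection is a recorded
  warning, not an error.

What the generator does **not** emulate: sensor physics, field spread /
volume conduction (so zero-lag artifacts that motivate PLI in real data
are absent — here PLI is exercised via explicit lags), source-leakage
correlations, non-stationarity across epochs, and amplitude–phase
coupling. Passing tests therefore validate the estimators and the model
logic, not robustness to those real-data confounds.

## Design choices where the design was open

- Log transform of tract counts: after averaging, weights are rescaled so
  the max maps to e − 1, passed through log1p, then max-normalized —
  bounded, monotone, zero-preserving; the raw tract-count scale of any
  particular dataset is irrelevant after the final normalization.
- Node strength = weighted degree (sum of weights), not binarized degree.
- Inter-region distances are Euclidean distances between region
  barycenters (supplied coordinates).
- Coupling model for synthetic cohorts is shared-phase mixing rather than
  a simulated oscillator network, so empirical-pipeline tests do not
  depend on the simulator module.
- Compensation sweep defaults: 32-node synthetic connectome, 8 × 8 grid
  with K geometric over 1.5 decades and v linear on 1–30 m/s, 3 replicate
  seeds per cell, d = 3. The metastable regime is the higher-mean
  component of a two-component Gaussian mixture (EM, 10 restarts) on
  pooled metastability values, with a top-quartile fallback if the fit
  degenerates. Isolines are marching-squares contours with linear
  interpolation; the longest connected path is kept.

## Known limitations

- Explicit Euler for the delay ODE and SDE: first-order accuracy,
  adequate at the default steps (guarded by the dt-halving test) but not
  for stiff or long-delay extremes.
- No linear stability analysis of coherent branches; dominance by
  largest r₀ is a proxy and can mislabel the attracting branch deep in
  multistable regions.
- The two-component mixture assumes the metastability distribution is
  bimodal; very small grids or noise-free sweeps may fall back to the
  quartile rule.
- Per-epoch PLV is a positively biased estimator at low locking; compare
  against surrogate nulls, not against zero.
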