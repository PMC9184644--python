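# synchrocomp

Tools for studying **compensatory reorganization of alpha-band phase
locking**: why the brain's peak alpha frequency (PAF) can slow with age
while inter-regional phase locking is preserved.

The package has two coupled halves:

1. **A whole-brain oscillator model.** Kuramoto phase oscillators with
   transmission delays,

   θ̇ᵢ = ωᵢ + (K/N) Σⱼ cᵢⱼ sin(θⱼ(t − τᵢⱼ) − θᵢ) + d ζ(t),

   either all-to-all (cᵢⱼ = 1, uniform τ) or on a structural connectome
   with per-pair delays τᵢⱼ = Dᵢⱼ/v set by inter-node distance and a
   cortical conduction velocity v. For Lorentzian natural frequencies
   g(ω) with center μ and half-width γ, the Ott–Antonsen reduction gives
   an exact delay ODE for the order parameter z, whose rotating-wave
   steady states z = r₀e^{iΩt} satisfy

   Ω = μ − K sin Ωτ + γ tan Ωτ,  r₀² = 1 − 2γ/(K cos Ωτ),

   with coherent solutions existing iff cos Ωτ ≥ 2γ/K. Delays depress
   the collective frequency Ω below μ; the lost synchrony can be bought
   back by raising K — the compensation mechanism. Sweeps over (K, v)
   extract iso-PLV contours and measure frequency depression along them.

2. **An MEG-style empirical pipeline.** Welch spectra → semi-log
   periodic + aperiodic spectral model (offset b, exponent χ, Gaussian
   peaks a·exp(−(F−c)²/2w²)) → per-subject PAF → band-pass + Hilbert
   phases → PLV/PLI in lower-alpha (6–10 Hz), upper-alpha (10–14 Hz) and
   the subject-specific band (PAF ± 2 Hz) → Pearson age trends and
   epoch-shuffle surrogate significance.

Everything runs end to end on synthetic data with known ground truth
(`synchrocomp.synthetic_data`): aging cohorts whose true PAF declines
linearly with age, channels phase-coupled at the subject's own PAF, and
random geometric connectomes. No downloads are required.

## Worked example

Depression of the synchronization frequency by delay, against theory:

```python
from synchrocomp.kuramoto import LorentzianSpec, simulate_uniform, \
    locked_cluster_frequency
from synchrocomp.oa_theory import solve_transcendental

spec = LorentzianSpec(mu=10.0, gamma=1.0)       # Hz
for tau in (0.0, 0.010, 0.020):                 # s
    traj = simulate_uniform(n=1000, K=8.0, tau=tau, spec=spec, seed=2)
    f = locked_cluster_frequency(traj)
    branches = solve_transcendental(K=8.0, tau=tau, spec=spec)
    print(f"tau={tau*1e3:4.0f} ms  sim {f:6.3f} Hz   "
          f"theory {branches[0].Omega:6.3f} Hz  r0={branches[0].r0:.3f}")
```

```
tau=   0 ms  sim 10.045 Hz   theory 10.000 Hz  r0=0.866
tau=  10 ms  sim  7.076 Hz   theory  7.047 Hz  r0=0.850
tau=  20 ms  sim  5.634 Hz   theory  5.647 Hz  r0=0.819
```

With no delay the network locks at the center frequency μ = 10 Hz with
r₀ = √(1 − 2γ/K); a 10 ms delay drags the locked cluster down to ≈ 7 Hz,
in agreement with the dominant root of the frequency equation.

The two end-to-end demos:

```sh
synchrocomp demo-empirical --out out_emp --subjects 60 --seed 0
synchrocomp demo-model     --out out_mod --nodes 32 --seed 1
```

`demo-empirical` prints the cohort's Pearson age trends — PAF declining
(r < 0, p ≪ 0.05), fixed lower/upper alpha bands drifting, and the
subject-specific band statistically flat — and writes per-subject tables.
`demo-model` runs the (K, v) sweep, delineates the metastable regime from
the bimodal metastability distribution, and reports the frequency drop
along iso-PLV contours (Spearman ρ(v, f) ≈ 1: frequency falls as
conduction slows, while phase locking is held constant).

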