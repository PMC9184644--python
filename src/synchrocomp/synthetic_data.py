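"""Synthetic connectomes, coupled oscillatory signals, and aging cohorts.

Everything downstream — spectral parameterization, phase locking, the
network model — is exercised against data generated here with known ground
truth: a cohort whose true peak alpha frequency (PAF) declines linearly
with age on top of a 1/f background, channels phase-coupled at the
subject's own PAF with a fixed inter-channel lag, and random geometric
connectomes with distance-dependent weight decay.

Signal synthesis: the alpha rhythm is a constant-amplitude cosine of a
stochastically wandering phase (Brownian phase diffusion sets the ~1 Hz
peak width), superposed on Gaussian noise spectrally shaped to a power-law
background. Channel k's alpha phase is

    theta_k(t) = Theta(t) + k * lag + (1 - coupling) * eta_k(t)

with a common wandering phase Theta at the target carrier and independent
per-channel phase-noise processes eta_k, so the true inter-channel phase
locking is a known monotone function of ``coupling`` (exactly 1 at
coupling=1 with no measurement noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .connectome import Connectome, validate_connectome
from .phase_locking import EpochedSignals

__all__ = [
    "SyntheticConnectomeSpec",
    "CohortSpec",
    "SubjectRecord",
    "make_synthetic_connectome",
    "make_coupled_phases",
    "make_coupled_signals",
    "make_cohort",
]

# Brownian phase-diffusion coefficient (rad^2/s). A Brownian-phase cosine has
# a Lorentzian line with HWHM = D / (4 pi) Hz; D = 2 pi gives a ~1 Hz FWHM
# alpha peak. The peak width of real subjects is a generator choice.
PHASE_DIFFUSION = 2.0 * np.pi


@dataclass(frozen=True)
class SyntheticConnectomeSpec:
    """Random geometric connectome with exponential distance decay.

    Coordinates are drawn uniformly inside a sphere of radius
    ``coordinate_scale`` (mm), giving inter-node distances on the tens-of-mm
    scale of cortical parcellations; weights decay as exp(-D/decay_length)
    with multiplicative log-normal noise, and a random fraction ``density``
    of off-diagonal pairs is retained.
    """

    n_nodes: int = 68
    density: float = 1.0
    decay_length: float = 80.0          # mm
    coordinate_scale: float = 140.0     # mm sphere radius
    weight_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")


def make_synthetic_connectome(spec: SyntheticConnectomeSpec) -> Connectome:
    """Generate a validated synthetic connectome from ``spec``.

    Deterministic in the spec (including its seed). If the retained edge
    set leaves the graph disconnected, a warning string is recorded in
    ``meta['warnings']`` rather than raising.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    # uniform in a ball: scale direction vectors by U^(1/3)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    coords = spec.coordinate_scale * v * rng.uniform(size=(n, 1)) ** (1 / 3)
    D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)

    w = np.exp(-D / spec.decay_length)
    if spec.weight_noise_sd > 0:
        noise = rng.lognormal(0.0, spec.weight_noise_sd, size=(n, n))
        noise = np.sqrt(noise * noise.T)       # keep symmetry
        w = w * noise
    mask = rng.uniform(size=(n, n)) < spec.density
    mask = np.triu(mask, k=1)
    mask = mask | mask.T
    w = np.where(mask, w, 0.0)
    np.fill_diagonal(w, 0.0)
    if w.max() > 0:
        w = w / w.max()

    meta: dict = {"spec": spec}
    n_comp, _ = connected_components(w > 0, directed=False)
    if n_comp > 1:
        meta["warnings"] = [f"graph has {n_comp} connected components"]
    c = Connectome(weights=w, distances=D,
                   labels=[f"roi{i:02d}" for i in range(n)],
                   coordinates=coords, meta=meta)
    return validate_connectome(c)


def _brownian_phase(rng, n_samples: int, dt: float,
                    diffusion: float = PHASE_DIFFUSION) -> np.ndarray:
    steps = np.sqrt(diffusion * dt) * rng.standard_normal(n_samples)
    steps[0] = rng.uniform(0, 2 * np.pi)       # random initial phase
    return np.cumsum(steps)


def make_coupled_phases(n_channels: int, fs: float, n_samples: int,
                        carrier: float, lag: float, coupling: float,
                        rng) -> np.ndarray:
    """Phase time courses (channels x samples) of the shared-phase model.

    The independent per-channel phase noise is i.i.d. uniform on
    (-pi, pi] per sample, so at coupling=0 the pairwise phase differences
    are exchangeable uniform angles and the phase-locking value follows the
    null resultant-length distribution of T independent unit vectors.
    """
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must lie in [0, 1]")
    t = np.arange(n_samples) / fs
    common = 2 * np.pi * carrier * t + _brownian_phase(rng, n_samples, 1 / fs)
    phases = np.empty((n_channels, n_samples))
    for k in range(n_channels):
        eta = rng.uniform(-np.pi, np.pi, size=n_samples) if coupling < 1 else 0.0
        phases[k] = common + k * lag + (1.0 - coupling) * eta
    return phases


def make_coupled_signals(n_channels: int, fs: float, duration: float,
                         carrier: float = 10.0, lag: float = 0.0,
                         coupling: float = 1.0, noise_sd: float = 0.0,
                         seed=None, epoch_length: float = 5.0) -> EpochedSignals:
    """Cosine signals with controllable inter-channel phase coupling.

    ``duration`` (s) is cut into ``epoch_length`` epochs; a duration
    shorter than one epoch is an error. ``fs`` must satisfy Nyquist for
    the carrier.
    """
    if fs <= 2 * carrier:
        raise ValueError("fs must exceed twice the carrier frequency")
    n_per = int(round(epoch_length * fs))
    n_total = int(round(duration * fs))
    n_epochs = n_total // n_per
    if n_epochs < 1:
        raise ValueError(f"duration {duration:g} s is shorter than one "
                         f"{epoch_length:g} s epoch")
    rng = np.random.default_rng(seed)
    data = np.empty((n_channels, n_epochs, n_per))
    for e in range(n_epochs):
        ph = make_coupled_phases(n_channels, fs, n_per, carrier, lag, coupling, rng)
        data[:, e, :] = np.cos(ph)
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return EpochedSignals(data=data, fs=fs, epoch_length=epoch_length)


def _powerlaw_noise(rng, n_samples: int, fs: float, exponent: float,
                    scale: float = 1.0) -> np.ndarray:
    """Gaussian noise with one-sided PSD ``scale / f^exponent`` (f in Hz)."""
    freqs = np.fft.rfftfreq(n_samples, 1 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = np.sqrt(scale * freqs[1:] ** (-exponent))
    spec = amp * (rng.standard_normal(freqs.size)
                  + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n_samples)
    # normalize so the realized PSD matches scale/f^exponent
    return x * np.sqrt(n_samples * fs / 2)


@dataclass(frozen=True)
class CohortSpec:
    """Aging cohort with linearly declining true PAF.

    ``paf_intercept`` is the expected PAF at the youngest age;
    ``paf_slope`` (Hz/year, typically negative) moves it with age;
    per-subject Gaussian scatter ``paf_noise_sd`` is added on top. Channels
    within a subject are phase-coupled at the subject's own PAF with
    strength ``coupling_strength`` and inter-channel lag ``coupling_lag``
    (radians), so subject-specific-band locking is age-invariant by
    construction while PAF declines.
    """

    n_subjects: int = 60
    age_range: tuple[float, float] = (18.0, 88.0)
    paf_intercept: float = 10.5         # Hz at the youngest age
    paf_slope: float = -0.03            # Hz / year
    paf_noise_sd: float = 0.4           # Hz
    aperiodic_exponent_range: tuple[float, float] = (0.8, 1.2)
    alpha_amplitude: float = 2.0        # signal units (cosine amplitude)
    channel_count: int = 8
    fs: float = 100.0
    epoch_length: float = 5.0
    n_epochs: int = 24
    coupling_lag: float = np.pi / 4
    coupling_strength: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.fs <= 2 * (self.paf_intercept + 4):
            raise ValueError("fs must exceed 2*(paf_intercept + 4) Hz")
        n = self.fs * self.epoch_length
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_length * fs must be an integer")


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    signals: EpochedSignals
    true_paf: float
    aperiodic_exponent: float = field(default=np.nan)


def _subject_signals(spec: CohortSpec, paf: float, exponent: float,
                     rng) -> EpochedSignals:
    n_per = int(round(spec.epoch_length * spec.fs))
    data = np.empty((spec.channel_count, spec.n_epochs, n_per))
    # The 1/f background is higher at lower frequencies, so a fixed alpha
    # amplitude would give low-PAF subjects a lower in-band SNR — an
    # amplitude-driven phase-locking confound on top of the intended
    # age-invariant coupling. Scale the amplitude so the peak-to-background
    # ratio at the subject's PAF equals that of a 10 Hz subject.
    amp = spec.alpha_amplitude * (paf / 10.0) ** (-exponent / 2)
    for e in range(spec.n_epochs):
        ph = make_coupled_phases(spec.channel_count, spec.fs, n_per, paf,
                                 spec.coupling_lag, spec.coupling_strength, rng)
        alpha = amp * np.cos(ph)
        for ch in range(spec.channel_count):
            bg = _powerlaw_noise(rng, n_per, spec.fs, exponent)
            data[ch, e, :] = alpha[ch] + bg
    return EpochedSignals(data=data, fs=spec.fs, epoch_length=spec.epoch_length)


def make_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the synthetic aging cohort.

    Ages are uniform on ``age_range``; each subject's true PAF is the
    linear age trend plus Gaussian scatter, resampled (up to 100 times)
    if it falls outside the analyzable band (4, fs/2 - 4) Hz. Deterministic
    in the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    lo_age, hi_age = spec.age_range
    records = []
    for i in range(spec.n_subjects):
        age = rng.uniform(lo_age, hi_age)
        base = spec.paf_intercept + spec.paf_slope * (age - lo_age)
        for attempt in range(100):
            paf = base + rng.normal(0.0, spec.paf_noise_sd)
            if 4.0 < paf < spec.fs / 2 - 4.0:
                break
        else:
            raise ValueError(f"subject {i}: could not draw a PAF inside "
                             f"(4, {spec.fs/2 - 4:g}) Hz in 100 attempts")
        exponent = rng.uniform(*spec.aperiodic_exponent_range)
        sig = _subject_signals(spec, paf, exponent, rng)
        records.append(SubjectRecord(subject_id=f"sub{i:03d}", age=float(age),
                                     signals=sig, true_paf=float(paf),
                                     aperiodic_exponent=float(exponent)))
    return records
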