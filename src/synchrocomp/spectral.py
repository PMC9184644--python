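"""Power spectra and the periodic-plus-aperiodic spectral model.

The power spectrum of resting electrophysiological signals is treated as a
broadband 1/f-like background plus narrowband oscillatory peaks. In
semi-log space (log power vs linear frequency) the model is

    log P(F) = b - chi * log F + sum_m a_m exp(-(F - c_m)^2 / (2 w_m^2))

with offset b, aperiodic exponent chi, and up to M Gaussian peaks of
amplitude a (log-power units), center c (Hz) and width w (Hz). The center
of the largest alpha-range peak is the peak alpha frequency (PAF).
Natural logarithms are used throughout; the base only shifts b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

__all__ = [
    "PowerSpectrum",
    "SpectralModel",
    "PAFEstimate",
    "welch_psd",
    "fit_spectral_model",
    "extract_paf",
    "subject_paf",
]


@dataclass
class PowerSpectrum:
    """One-sided Welch power spectral density."""

    F: np.ndarray          # Hz, strictly increasing
    P: np.ndarray          # linear power units
    fs: float
    n_windows: int = 1


@dataclass
class SpectralModel:
    """Fitted aperiodic (b, chi) + Gaussian peak parameters."""

    offset: float                       # b, log-power
    exponent: float                     # chi
    peaks: list[tuple[float, float, float]]   # (a, c_Hz, w_Hz)
    fit_range: tuple[float, float] = (2.0, 20.0)
    max_peaks: int = 3
    goodness: float = np.nan            # R^2 in semi-log space
    converged: bool = True

    def evaluate(self, F: np.ndarray) -> np.ndarray:
        """Model prediction in semi-log space (natural-log power)."""
        F = np.asarray(F, float)
        out = self.offset - self.exponent * np.log(F)
        for a, c, w in self.peaks:
            out = out + a * np.exp(-((F - c) ** 2) / (2 * w**2))
        return out


@dataclass
class PAFEstimate:
    per_roi: list[float | None]
    subject_mean: float
    missing_fraction: float = 0.0
    models: list = field(default_factory=list, repr=False)


def welch_psd(x: np.ndarray, fs: float, window_length: float = 5.0,
              overlap: float = 0.5) -> PowerSpectrum:
    """Welch average periodogram with Hann taper.

    ``x`` may be 1-D (one continuous record) or 2-D (epochs x samples), in
    which case per-epoch spectra are averaged with windows confined to
    epochs (no cross-epoch leakage).
    """
    nper = int(round(window_length * fs))
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[-1] < nper:
        raise ValueError(f"signal shorter ({x.shape[-1]} samples) than one "
                         f"{window_length:g} s window ({nper} samples)")
    noverlap = int(round(nper * overlap))
    F, P = sps.welch(x, fs=fs, window="hann", nperseg=nper,
                     noverlap=noverlap, detrend="constant", axis=-1)
    step = nper - noverlap
    per_row = 1 + (x.shape[-1] - nper) // step
    P = P.mean(axis=0)
    return PowerSpectrum(F=F, P=P, fs=fs, n_windows=int(per_row * x.shape[0]))


def _robust_aperiodic_fit(logF, logP):
    """Linear semi-log fit of b - chi*logF, ignoring the top residual quartile.

    Peaks only push power upward, so the most positive residuals of an
    initial least-squares line are peak-contaminated and get dropped.
    """
    A = np.c_[np.ones_like(logF), -logF]
    coef, *_ = np.linalg.lstsq(A, logP, rcond=None)
    resid = logP - A @ coef
    keep = resid <= np.quantile(resid, 0.75)
    coef, *_ = np.linalg.lstsq(A[keep], logP[keep], rcond=None)
    return coef  # (b, chi)


def fit_spectral_model(psd: PowerSpectrum, fit_range: tuple[float, float] = (2.0, 20.0),
                       max_peaks: int = 3, peak_threshold_sd: float = 2.0,
                       min_peak_height: float = 0.1) -> SpectralModel:
    """Fit the semi-log periodic + aperiodic model to a Welch spectrum.

    Procedure: (1) robust aperiodic line fit ignoring the top residual
    quartile; (2) iterative extraction of up to ``max_peaks`` Gaussians from
    the flattened spectrum wherever its maximum exceeds
    ``peak_threshold_sd`` flattened-residual standard deviations (and an
    absolute floor); (3) joint least-squares refinement of all parameters.
    On refinement failure the aperiodic-only model is returned flagged
    ``converged=False``.
    """
    lo, hi = fit_range
    sel = (psd.F >= lo) & (psd.F <= hi)
    F = psd.F[sel]
    P = psd.P[sel]
    if F.size < 10:
        raise ValueError("fewer than 10 frequency bins in fit range")
    if np.any(P <= 0):
        raise ValueError("nonpositive power inside fit range")
    logF, logP = np.log(F), np.log(P)

    b, chi = _robust_aperiodic_fit(logF, logP)
    flat = logP - (b - chi * logF)

    peaks: list[tuple[float, float, float]] = []
    work = flat.copy()
    min_w = max(2 * (F[1] - F[0]), 0.25)
    for _ in range(max_peaks):
        thresh = max(peak_threshold_sd * np.std(work), min_peak_height)
        i = int(np.argmax(work))
        a0 = work[i]
        if a0 < thresh:
            break
        c0 = F[i]
        # half-height crossing gives a width guess
        half = a0 / 2
        li = i
        while li > 0 and work[li] > half:
            li -= 1
        ri = i
        while ri < len(work) - 1 and work[ri] > half:
            ri += 1
        fwhm = max(F[ri] - F[li], 2 * min_w)
        w0 = float(np.clip(fwhm / 2.355, min_w, (hi - lo) / 2))
        try:
            popt, _ = curve_fit(
                lambda f, a, c, w: a * np.exp(-((f - c) ** 2) / (2 * w**2)),
                F, work, p0=(a0, c0, w0),
                bounds=([0.0, lo, min_w], [np.inf, hi, (hi - lo) / 2]),
                maxfev=5000)
        except RuntimeError:
            break
        a, c, w = popt
        if a < thresh / 2:
            break
        peaks.append((float(a), float(c), float(w)))
        work = work - a * np.exp(-((F - c) ** 2) / (2 * w**2))

    def full_model(f, *p):
        b_, chi_ = p[0], p[1]
        out = b_ - chi_ * np.log(f)
        for m in range(len(peaks)):
            a_, c_, w_ = p[2 + 3 * m: 5 + 3 * m]
            out = out + a_ * np.exp(-((f - c_) ** 2) / (2 * w_**2))
        return out

    p0 = [b, chi] + [v for pk in peaks for v in pk]
    lower = [-np.inf, -np.inf] + [0.0, lo, min_w / 2] * len(peaks)
    upper = [np.inf, np.inf] + [np.inf, hi, hi - lo] * len(peaks)
    p0 = [float(np.clip(v, l, u)) for v, l, u in zip(p0, lower, upper)]
    converged = True
    try:
        popt, _ = curve_fit(full_model, F, logP, p0=p0, bounds=(lower, upper),
                            maxfev=10000)
        b, chi = popt[0], popt[1]
        peaks = [(float(popt[2 + 3 * m]), float(popt[3 + 3 * m]),
                  float(popt[4 + 3 * m])) for m in range(len(peaks))]
    except RuntimeError:
        peaks = []
        converged = False

    model = SpectralModel(offset=float(b), exponent=float(chi), peaks=peaks,
                          fit_range=fit_range, max_peaks=max_peaks,
                          converged=converged)
    pred = model.evaluate(F)
    ss_res = np.sum((logP - pred) ** 2)
    ss_tot = np.sum((logP - logP.mean()) ** 2)
    model.goodness = float(1 - ss_res / ss_tot) if ss_tot > 0 else np.nan
    return model


def extract_paf(model: SpectralModel,
                search_range: tuple[float, float] = (6.0, 14.0)) -> float | None:
    """Center of the largest-amplitude fitted peak inside the alpha search range."""
    in_range = [(a, c) for a, c, _ in model.peaks
                if search_range[0] <= c <= search_range[1]]
    if not in_range:
        return None
    return max(in_range)[1]


def subject_paf(spectra: list[PowerSpectrum],
                fit_range: tuple[float, float] = (2.0, 20.0),
                search_range: tuple[float, float] = (6.0, 14.0),
                max_peaks: int = 3) -> PAFEstimate:
    """Per-ROI spectral fits averaged into one subject-level PAF.

    Each region's spectrum is fitted independently; regions without an
    alpha-range peak are recorded as missing, and the subject PAF is the
    arithmetic mean over the remainder. Raises if every region is missing.
    """
    if not spectra:
        raise ValueError("need at least one ROI spectrum")
    per_roi: list[float | None] = []
    models = []
    for psd in spectra:
        m = fit_spectral_model(psd, fit_range=fit_range, max_peaks=max_peaks)
        models.append(m)
        per_roi.append(extract_paf(m, search_range=search_range))
    found = [v for v in per_roi if v is not None]
    if not found:
        raise ValueError("no ROI yielded an alpha-range peak")
    return PAFEstimate(per_roi=per_roi, subject_mean=float(np.mean(found)),
                       missing_fraction=1 - len(found) / len(per_roi),
                       models=models)
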