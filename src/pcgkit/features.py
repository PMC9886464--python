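"""Hand-crafted heart-sound features: 26 values per recording.

The feature vector concatenates, in a fixed documented order:

1.  ten time-domain statistics (RMS, shape factor, skewness, kurtosis, peak,
    impulse factor, crest factor, clearance factor, mean, std);
2.  three spectral-quality measures in dB (SNR, SINAD, THD) estimated from a
    Kaiser-windowed periodogram;
3.  thirteen mel-frequency cepstral coefficients (MFCC), the per-coefficient
    mean over 25 ms Hamming frames with 10 ms hop.

Skewness and kurtosis are the third and fourth standardized moments with
population (1/N) normalization; kurtosis is the raw moment (a Gaussian gives
3, no excess subtraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft
from scipy.signal import get_window, periodogram

from ._core import DegenerateInputError, ValidationError
from .io import Signal

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "time_domain_features",
    "spectral_quality_features",
    "mfcc_features",
    "mel",
    "extract_features",
]

TIME_DOMAIN_NAMES = (
    "rms", "shape_factor", "skewness", "kurtosis", "peak",
    "impulse_factor", "crest_factor", "clearance_factor", "mean", "std",
)
SPECTRAL_NAMES = ("snr_db", "sinad_db", "thd_db")
MFCC_NAMES = tuple(f"mfcc{i}" for i in range(1, 14))

#: Canonical order of the 26 features.
FEATURE_NAMES: tuple[str, ...] = TIME_DOMAIN_NAMES + SPECTRAL_NAMES + MFCC_NAMES


@dataclass(frozen=True)
class FeatureVector:
    """The 26 features of one recording, in :data:`FEATURE_NAMES` order."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (len(self.names),):
            raise ValidationError(
                f"expected {len(self.names)} feature values, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("feature values must be finite")
        object.__setattr__(self, "values", values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def time_domain_features(signal: Signal) -> dict[str, float]:
    """The ten time-domain statistics.

    ``std`` uses the sample (N-1) convention; the standardized moments use
    population (1/N) normalization, so a long Gaussian signal has kurtosis
    close to 3 and skewness close to 0.
    """
    x = signal.samples
    if x.size < 2:
        raise ValidationError("time-domain features need at least 2 samples")
    if np.max(x) == np.min(x):
        raise DegenerateInputError("constant signal: ratio features are undefined")
    mean = float(np.mean(x))
    centered = x - mean
    m2 = float(np.mean(centered**2))
    rms = float(np.sqrt(np.mean(x**2)))
    abs_mean = float(np.mean(np.abs(x)))
    peak = float(np.max(np.abs(x)))
    if abs_mean == 0 or rms == 0:
        raise DegenerateInputError("all-zero signal: ratio denominators vanish")
    return {
        "rms": rms,
        "shape_factor": rms / abs_mean,
        "skewness": float(np.mean(centered**3)) / m2**1.5,
        "kurtosis": float(np.mean(centered**4)) / m2**2,
        "peak": peak,
        "impulse_factor": peak / abs_mean,
        "crest_factor": peak / rms,
        "clearance_factor": peak / float(np.mean(np.sqrt(np.abs(x)))) ** 2,
        "mean": mean,
        "std": float(np.std(x, ddof=1)),
    }


def _expand_peak(pxx: np.ndarray, k: int) -> tuple[int, int]:
    """Half-open bin range of the spectral component peaking at bin ``k``.

    Extends left and right from the peak down to the nearest local minima,
    capturing window leakage around a tone without fixed-width assumptions.
    """
    lo = k
    while lo > 0 and pxx[lo - 1] < pxx[lo]:
        lo -= 1
    hi = k
    while hi < pxx.size - 1 and pxx[hi + 1] < pxx[hi]:
        hi += 1
    return lo, hi + 1


def spectral_quality_features(signal: Signal, n_harmonics: int = 6,
                              window: tuple = ("kaiser", 38)) -> dict[str, float]:
    """SNR, SINAD and THD in dB from a windowed periodogram.

    The fundamental is the largest non-DC component; harmonics are the local
    peaks near its first ``n_harmonics`` integer multiples.  Bins belonging
    to a component extend from its peak to the neighbouring spectral minima
    (leakage grouping).  Noise power is everything except DC, the fundamental
    and the harmonics.
    """
    x = signal.samples
    if x.size < 64:
        raise ValidationError("spectral-quality features need >= 64 samples")
    freqs, pxx = periodogram(x, fs=signal.rate, window=get_window(window, x.size))
    if np.max(pxx) <= 0:
        raise DegenerateInputError("flat/empty spectrum")

    used = np.zeros(pxx.size, dtype=bool)
    dc_lo, dc_hi = _expand_peak(pxx, 0)
    used[dc_lo:dc_hi] = True

    masked = np.where(used, -np.inf, pxx)
    k_fund = int(np.argmax(masked))
    if not np.isfinite(masked[k_fund]) or pxx[k_fund] == 0:
        raise DegenerateInputError("no non-DC spectral component")
    f_lo, f_hi = _expand_peak(pxx, k_fund)
    p_fund = float(pxx[f_lo:f_hi].sum())
    used[f_lo:f_hi] = True
    f0 = freqs[k_fund]

    df = freqs[1] - freqs[0]
    p_harm = 0.0
    for h in range(2, n_harmonics + 2):
        fh = h * f0
        if fh >= freqs[-1]:
            break
        k0 = int(round(fh / df))
        half = max(int(round(0.25 * f0 / df)), 2)
        lo = max(k0 - half, 1)
        hi = min(k0 + half + 1, pxx.size)
        k_peak = lo + int(np.argmax(pxx[lo:hi]))
        h_lo, h_hi = _expand_peak(pxx, k_peak)
        p_harm += float(pxx[h_lo:h_hi][~used[h_lo:h_hi]].sum())
        used[h_lo:h_hi] = True

    p_noise = float(pxx[~used].sum())
    if p_noise <= 0:
        p_noise = np.finfo(float).tiny
    if p_harm <= 0:
        p_harm = np.finfo(float).tiny
    return {
        "snr_db": 10 * np.log10(p_fund / p_noise),
        "sinad_db": 10 * np.log10(p_fund / (p_noise + p_harm)),
        "thd_db": 10 * np.log10(p_harm / p_fund),
    }


def mel(f):
    """Mel scale: mel(f) = 2595 * log10(1 + f / 700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, n_fft: int, rate: float) -> np.ndarray:
    """Triangular filters with edges equally spaced on the mel scale."""
    edges_hz = _mel_inv(np.linspace(0.0, mel(rate / 2.0), n_filters + 2))
    bin_freqs = np.arange(n_fft // 2 + 1) * rate / n_fft
    fbank = np.zeros((n_filters, bin_freqs.size))
    for i in range(n_filters):
        left, center, right = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        rising = (bin_freqs - left) / (center - left)
        falling = (right - bin_freqs) / (right - center)
        fbank[i] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fbank


def mfcc_features(signal: Signal, n_coeffs: int = 13, frame_len: float = 0.025,
                  hop: float = 0.010, n_filters: int = 26,
                  include_zeroth: bool = True) -> np.ndarray:
    """Recording-level MFCCs: per-coefficient mean over frames.

    Per frame: Hamming window, FFT power spectrum, triangular mel filterbank,
    natural log of filter energies, orthonormal type-II DCT.  By default the
    coefficients 0..``n_coeffs``-1 are retained (the 0th carries the
    log-energy); set ``include_zeroth=False`` to keep 1..``n_coeffs`` instead.
    """
    x = signal.samples
    frame = int(round(frame_len * signal.rate))
    step = int(round(hop * signal.rate))
    if frame < 2 or step < 1:
        raise ValidationError("frame/hop too short for the sample rate")
    if x.size < frame:
        raise ValidationError(
            f"signal of {x.size} samples is shorter than one {frame}-sample frame"
        )
    n_fft = 1 << (frame - 1).bit_length()
    win = np.hamming(frame)
    fbank = _mel_filterbank(n_filters, n_fft, signal.rate)

    n_frames = 1 + (x.size - frame) // step
    idx = np.arange(frame)[None, :] + step * np.arange(n_frames)[:, None]
    frames = x[idx] * win
    power = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
    energies = power @ fbank.T
    log_e = np.log(np.maximum(energies, np.finfo(float).tiny))
    coeffs = dct(log_e, type=2, norm="ortho", axis=1)
    if include_zeroth:
        kept = coeffs[:, :n_coeffs]
    else:
        kept = coeffs[:, 1:n_coeffs + 1]
    return kept.mean(axis=0)


def extract_features(signal: Signal) -> FeatureVector:
    """Extract the full 26-feature vector from a (resampled) recording."""
    td = time_domain_features(signal)
    sq = spectral_quality_features(signal)
    mf = mfcc_features(signal)
    values = np.concatenate([
        [td[name] for name in TIME_DOMAIN_NAMES],
        [sq[name] for name in SPECTRAL_NAMES],
        mf,
    ])
    return FeatureVector(values)
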