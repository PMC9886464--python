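"""Continuous wavelet transform scalograms and CNN-ready image export.

The CWT uses the generalized Morse wavelet (symmetry parameter gamma = 3,
time-bandwidth product P^2 = 60), evaluated as a frequency-domain filter
bank with logarithmically spaced center frequencies (12 voices per octave by
default).  The analytic Morse wavelet of order (beta, gamma) is, for
omega > 0,

    Psi(omega) = 2 * (e*gamma/beta)^(beta/gamma) * omega^beta * exp(-omega^gamma)

with beta = P^2 / gamma and peak (center) frequency omega_p = (beta/gamma)^(1/gamma).
The filter-bank frequency axis spans from near the Nyquist frequency down to
the lowest frequency whose wavelet support still fits the signal.

Scalograms are exported as 224 x 224 x 3 RGB images (per-image min-max
scaling, fixed 128-level jet colormap, bilinear resize) in class-named
folders, ready for an external image-classifier trainer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
from PIL import Image
from scipy.fft import fft, ifft

from ._core import AudioIOError, ValidationError
from .io import Signal

__all__ = ["Scalogram", "cwt_scalogram", "to_rgb_image", "export_image_dataset",
           "morse_wavelet_ft"]

MORSE_GAMMA = 3.0
MORSE_TIME_BANDWIDTH = 60.0
IMAGE_SIZE = 224
COLORMAP_LEVELS = 128


@dataclass(frozen=True)
class Scalogram:
    """CWT magnitude matrix with its frequency (rows) and time (columns) axes."""

    magnitude: np.ndarray   # (n_freqs, n_times), >= 0
    freqs: np.ndarray       # Hz, strictly decreasing
    times: np.ndarray       # seconds, strictly increasing

    def __post_init__(self) -> None:
        if self.magnitude.ndim != 2 or self.magnitude.size == 0:
            raise ValidationError("scalogram magnitude must be a non-empty matrix")
        if np.any(self.magnitude < 0):
            raise ValidationError("scalogram magnitudes must be non-negative")
        if self.freqs.size > 1 and not np.all(np.diff(self.freqs) < 0):
            raise ValidationError("frequency axis must be strictly decreasing")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("time axis must be strictly increasing")


def morse_wavelet_ft(omega: np.ndarray, gamma: float = MORSE_GAMMA,
                     time_bandwidth: float = MORSE_TIME_BANDWIDTH) -> np.ndarray:
    """Fourier transform of the analytic Morse wavelet on omega (rad/sample).

    Peak-normalized so Psi(omega_peak) = 2; zero for omega <= 0.
    """
    beta = time_bandwidth / gamma
    omega = np.asarray(omega, dtype=np.float64)
    out = np.zeros_like(omega)
    pos = omega > 0
    # log-space evaluation: log(2) + (beta/gamma)(1 + log(gamma/beta)) + beta*log(w) - w^gamma
    log_amp = (beta / gamma) * (1.0 + np.log(gamma / beta))
    out[pos] = 2.0 * np.exp(log_amp + beta * np.log(omega[pos]) - omega[pos] ** gamma)
    return out


def _center_frequencies(n_samples: int, rate: float, voices_per_octave: int,
                        time_bandwidth: float) -> np.ndarray:
    """Descending geometric grid of center frequencies covering (f_min, Nyquist]."""
    f_max = rate / 2.0
    # lowest frequency whose wavelet (two time standard deviations each side,
    # sigma_t ~ sqrt(P^2)/omega_c) still fits inside the signal
    f_min = 2.0 * np.sqrt(time_bandwidth) * rate / (np.pi * n_samples)
    if f_min >= f_max:
        raise ValidationError(
            f"signal of {n_samples} samples is shorter than the longest wavelet support"
        )
    n_octaves = np.log2(f_max / f_min)
    n_freqs = int(np.floor(n_octaves * voices_per_octave)) + 1
    return f_max * 2.0 ** (-np.arange(n_freqs) / voices_per_octave)


def cwt_scalogram(signal: Signal, voices_per_octave: int = 12,
                  gamma: float = MORSE_GAMMA,
                  time_bandwidth: float = MORSE_TIME_BANDWIDTH) -> Scalogram:
    """Morse-wavelet CWT magnitude scalogram of a (normalized) signal.

    Rows are center frequencies in Hz, descending; columns are time steps at
    the signal's sample rate.
    """
    x = signal.samples
    n = x.size
    if n < 64:
        raise ValidationError("signal too short for a CWT filter bank")
    beta = time_bandwidth / gamma
    omega_p = (beta / gamma) ** (1.0 / gamma)
    freqs = _center_frequencies(n, signal.rate, voices_per_octave, time_bandwidth)

    omega = 2.0 * np.pi * np.fft.fftfreq(n)  # rad/sample, signed
    scales = omega_p * signal.rate / (2.0 * np.pi * freqs)
    filters = morse_wavelet_ft(scales[:, None] * omega[None, :], gamma, time_bandwidth)
    coeffs = ifft(fft(x)[None, :] * filters, axis=1)
    return Scalogram(
        magnitude=np.abs(coeffs),
        freqs=freqs,
        times=np.arange(n) / signal.rate,
    )


def to_rgb_image(scalogram: Scalogram, size: int = IMAGE_SIZE) -> np.ndarray:
    """Render a scalogram as a ``size x size x 3`` uint8 RGB array.

    Magnitudes are min-max scaled per image, quantized to a fixed 128-level
    jet colormap, and bilinearly resized.  A constant-magnitude input maps
    to the colormap's lowest level.
    """
    mag = scalogram.magnitude
    lo, hi = float(mag.min()), float(mag.max())
    if hi > lo:
        scaled = (mag - lo) / (hi - lo)
    else:
        scaled = np.zeros_like(mag)
    cmap = matplotlib.colormaps["jet"].resampled(COLORMAP_LEVELS)
    levels = np.minimum((scaled * COLORMAP_LEVELS).astype(int), COLORMAP_LEVELS - 1)
    rgb = (cmap(levels / (COLORMAP_LEVELS - 1))[:, :, :3] * 255).astype(np.uint8)
    img = Image.fromarray(rgb, mode="RGB").resize((size, size), Image.BILINEAR)
    return np.asarray(img)


def export_image_dataset(signals, out_dir: str | Path, size: int = IMAGE_SIZE,
                         normalize: bool = True) -> list[dict]:
    """Write one scalogram PNG per labeled recording into class folders.

    All recordings must share one sample rate (resample first otherwise).
    Returns the manifest rows (file, label) that are also written to
    ``manifest.csv``.  The export is idempotent: rerunning produces
    byte-identical files.
    """
    from .io import zscore_normalize

    signals = list(signals)
    if not signals:
        raise ValidationError("no signals to export")
    rates = {s.rate for s in signals}
    if len(rates) > 1:
        raise ValidationError(
            f"mixed sample rates {sorted(rates)}: resample all recordings "
            "to a common rate (e.g. resample_to(signal, 8000)) before export"
        )
    if any(s.label is None for s in signals):
        raise ValidationError("every signal must carry a class label")

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise AudioIOError(f"cannot create output directory {out_dir}: {exc}") from exc

    manifest: list[dict] = []
    counters: dict[str, int] = {}
    for sig in signals:
        idx = counters.get(sig.label, 0)
        counters[sig.label] = idx + 1
        rel = f"{sig.label}/{sig.label}_{idx:04d}.png"
        path = out_dir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        prepared = zscore_normalize(sig) if normalize else sig
        rgb = to_rgb_image(cwt_scalogram(prepared), size=size)
        try:
            Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
        except OSError as exc:
            raise AudioIOError(f"cannot write image {path}: {exc}") from exc
        manifest.append({"file": rel, "label": sig.label})
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["file", "label"])
        writer.writeheader()
        writer.writerows(manifest)
    return manifest
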