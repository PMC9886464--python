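"""Phonocardiogram audio I/O and canonical preprocessing.

Every downstream stage of the toolkit expects a mono signal at 8000 Hz,
optionally z-scored to zero mean and unit variance.  This module reads and
writes RIFF/WAV files (PCM16 and float32), averages multi-channel input to
mono, resamples with band-limited polyphase interpolation, and applies the
z-score normalization x_new = (x - mu) / sigma.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from ._core import CLASSES, AudioIOError, DegenerateInputError, ValidationError

__all__ = [
    "Signal",
    "read_wav",
    "write_wav",
    "resample_to",
    "zscore_normalize",
    "write_manifest",
    "read_manifest",
    "TARGET_RATE",
]

#: Sample rate every recording is resampled to before analysis.
TARGET_RATE = 8000


@dataclass(frozen=True)
class Signal:
    """A mono heart-sound recording.

    Parameters
    ----------
    samples
        Dimensionless amplitude sequence, 1-D, finite, non-empty.
    rate
        Sampling rate in Hz, > 0.
    label
        Optional diagnostic class tag, one of ``AS, MR, MS, MVP, N``.
    """

    samples: np.ndarray
    rate: float
    label: str | None = field(default=None)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValidationError("Signal.samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("Signal.samples must be finite-valued")
        if not self.rate > 0:
            raise ValidationError(f"Signal.rate must be positive, got {self.rate}")
        if self.label is not None and self.label not in CLASSES:
            raise ValidationError(
                f"unknown class label {self.label!r}; expected one of {CLASSES}"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


def read_wav(path: str | Path, label: str | None = None) -> Signal:
    """Read a RIFF/WAV file as a mono :class:`Signal`.

    Multi-channel audio is averaged to mono.  Integer PCM is rescaled to
    [-1, 1); float data is passed through unchanged.  The file's sample rate
    is preserved (resample separately with :func:`resample_to`).
    """
    path = Path(path)
    if not path.exists():
        raise AudioIOError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # wavfile raises bare ValueError on corrupt input
        raise AudioIOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValidationError(f"zero-length audio in {path}")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        offset = 0.0
        if info.min == 0:  # unsigned PCM (e.g. uint8) is offset binary
            offset = (info.max + 1) / 2.0
            scale = offset
        data = (data.astype(np.float64) - offset) / scale
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return Signal(data, float(rate), label=label)


def write_wav(path: str | Path, signal: Signal, dtype: str = "float32") -> None:
    """Write a :class:`Signal` to a WAV file as ``float32`` or ``pcm16``."""
    path = Path(path)
    if dtype == "float32":
        data = signal.samples.astype(np.float32)
    elif dtype == "pcm16":
        clipped = np.clip(signal.samples, -1.0, 32767.0 / 32768.0)
        data = np.round(clipped * 32768.0).astype(np.int16)
    else:
        raise ValidationError(f"unsupported WAV dtype {dtype!r}")
    try:
        wavfile.write(path, int(round(signal.rate)), data)
    except OSError as exc:
        raise AudioIOError(f"cannot write WAV file {path}: {exc}") from exc


def resample_to(signal: Signal, target_rate: float = TARGET_RATE) -> Signal:
    """Resample to ``target_rate`` with band-limited polyphase filtering.

    Anti-aliasing is applied on downsampling; a signal already at the target
    rate is returned unchanged.  Duration is preserved to within one sample
    period.
    """
    if not target_rate > 0:
        raise ValidationError("target_rate must be positive")
    if signal.rate == target_rate:
        return signal
    ratio = Fraction(target_rate / signal.rate).limit_denominator(10_000)
    # Kaiser beta 12 keeps passband ripple well below 1e-3 relative error
    out = resample_poly(signal.samples, ratio.numerator, ratio.denominator,
                        window=("kaiser", 12.0))
    return Signal(out, float(target_rate), label=signal.label)


def zscore_normalize(signal: Signal, ddof: int = 1) -> Signal:
    """Normalize to zero mean and unit standard deviation.

    ``ddof=1`` (sample deviation, the default) matches the convention of
    mainstream numerics environments; set ``ddof=0`` for the population form.
    """
    x = signal.samples
    if x.size < 2:
        raise ValidationError("z-score normalization needs at least 2 samples")
    sigma = x.std(ddof=ddof)
    if sigma == 0:
        raise DegenerateInputError("constant signal: standard deviation is zero")
    return replace(signal, samples=(x - x.mean()) / sigma)


def write_manifest(path: str | Path, rows: list[dict]) -> None:
    """Write a labeled-dataset manifest CSV (filename, label, rate, duration)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["filename", "label", "rate", "duration"])
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def read_manifest(path: str | Path) -> list[dict]:
    """Read a manifest CSV written by :func:`write_manifest`."""
    path = Path(path)
    if not path.exists():
        raise AudioIOError(f"no such manifest: {path}")
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
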