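"""Synthetic phonocardiogram simulator for the five diagnostic classes.

Heart sounds are modelled phenomenologically, not hemodynamically: the S1 and
S2 valve-closure sounds are Gaussian-windowed tone bursts, and murmurs are
envelope-modulated band-passed white noise placed in the systolic or diastolic
interval of each cardiac cycle.  The class recipes follow textbook
auscultation findings:

* ``N``    — S1/S2 bursts only.
* ``AS``   — systolic ejection murmur, diamond (crescendo–decrescendo)
  envelope, mid-frequency band.
* ``MR``   — holosystolic murmur with a plateau envelope.
* ``MS``   — low-pitched diastolic rumble with a decrescendo envelope.
* ``MVP``  — mid-systolic click followed by a late-systolic crescendo murmur.

All randomness flows from an integer seed, so any recording is reproducible
bit-for-bit.  Generated audio never clips (max |sample| <= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from ._core import CLASSES, ValidationError
from .io import Signal, write_manifest, write_wav

__all__ = ["CycleRecipe", "DEFAULT_RECIPES", "synth_recording", "synth_dataset"]


@dataclass(frozen=True)
class CycleRecipe:
    """Parameters of one cardiac cycle for the simulator.

    Times are either seconds (``s1_dur``, ``s2_dur``) or fractions of the
    cycle (``murmur_window``, ``click``); frequencies are Hz.  ``noise_snr``
    is the additive-white-noise level in dB relative to the clean signal
    (``inf`` disables noise).
    """

    heart_rate: float = 75.0          # beats per minute
    s1_freq: float = 45.0             # S1 burst center frequency
    s2_freq: float = 90.0             # S2 burst center frequency
    s1_dur: float = 0.12              # seconds
    s2_dur: float = 0.09              # seconds
    s2_onset_frac: float = 0.35       # S2 onset as fraction of the cycle
    murmur_window: tuple[float, float] | None = None   # fraction of cycle
    murmur_band: tuple[float, float] | None = None     # Hz (low, high)
    murmur_envelope: str = "diamond"  # diamond | plateau | decrescendo | late-crescendo
    murmur_amp: float = 0.35          # murmur RMS relative to S1 peak
    click: tuple[float, float] | None = None           # (cycle fraction, Hz)
    noise_snr: float = 25.0           # dB

    def __post_init__(self) -> None:
        cycle = 60.0 / self.heart_rate
        if not 0 < self.s1_dur + self.s2_dur < cycle:
            raise ValidationError("S1 + S2 duration must fit inside one cycle")
        if self.murmur_window is not None:
            lo, hi = self.murmur_window
            if not (0 <= lo < hi <= 1):
                raise ValidationError("murmur_window must lie inside one cycle")
        if self.murmur_envelope not in ("diamond", "plateau", "decrescendo", "late-crescendo"):
            raise ValidationError(f"unknown murmur envelope {self.murmur_envelope!r}")


#: Fixed per-class recipes (auscultation phenomenology; see docs/methods.md).
DEFAULT_RECIPES: dict[str, CycleRecipe] = {
    "N": CycleRecipe(),
    "AS": CycleRecipe(
        murmur_window=(0.10, 0.33),
        murmur_band=(100.0, 400.0),
        murmur_envelope="diamond",
        murmur_amp=0.35,
    ),
    "MR": CycleRecipe(
        murmur_window=(0.04, 0.37),
        murmur_band=(100.0, 300.0),
        murmur_envelope="plateau",
        murmur_amp=0.30,
    ),
    "MS": CycleRecipe(
        murmur_window=(0.55, 0.95),
        murmur_band=(30.0, 80.0),
        murmur_envelope="decrescendo",
        murmur_amp=0.50,
    ),
    "MVP": CycleRecipe(
        murmur_window=(0.24, 0.36),
        murmur_band=(150.0, 400.0),
        murmur_envelope="late-crescendo",
        murmur_amp=0.40,
        click=(0.21, 300.0),
    ),
}

#: Within-class jitter ranges used by :func:`synth_recording`.
HEART_RATE_JITTER = 0.10   # +/- 10 % of the recipe heart rate
MURMUR_AMP_JITTER = 0.20   # +/- 20 % of the recipe murmur amplitude
PEAK_LEVEL = 0.9           # clean-signal peak after scaling


def _tone_burst(t: np.ndarray, center: float, dur: float, freq: float,
                amp: float, phase: float) -> np.ndarray:
    """Gaussian-windowed sinusoid of ~``dur`` support centred at ``center``."""
    sigma = dur / 6.0  # +/- 3 sigma support
    mask = np.abs(t - center) <= dur / 2
    out = np.zeros_like(t)
    tt = t[mask] - center
    out[mask] = amp * np.exp(-0.5 * (tt / sigma) ** 2) * np.sin(2 * np.pi * freq * tt + phase)
    return out


def _envelope(u: np.ndarray, kind: str) -> np.ndarray:
    """Murmur amplitude envelope over normalized window position u in [0, 1]."""
    if kind == "diamond":
        return 1.0 - np.abs(2.0 * u - 1.0)
    if kind == "plateau":
        ramp = 0.1
        return np.clip(np.minimum(u / ramp, (1.0 - u) / ramp), 0.0, 1.0)
    if kind == "decrescendo":
        env = np.exp(-3.0 * u)
        taper = np.clip(np.minimum(u / 0.05, (1.0 - u) / 0.05), 0.0, 1.0)
        return env * taper
    if kind == "late-crescendo":
        return u**2 * np.clip((1.0 - u) / 0.1, 0.0, 1.0)
    raise ValidationError(f"unknown murmur envelope {kind!r}")


def _band_noise(n: int, band: tuple[float, float], rate: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (4th-order Butterworth, zero-phase)."""
    lo, hi = band
    if hi >= rate / 2:
        raise ValidationError("murmur band upper edge must be below Nyquist")
    # Pad so the filter transient does not leak outside the murmur window.
    pad = max(int(0.1 * rate), 32)
    sos = butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:-pad]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def synth_recording(class_label: str, duration: float = 3.0, rate: float = 8000.0,
                    seed: int = 0, recipe: CycleRecipe | None = None) -> Signal:
    """Generate one labeled synthetic heart-sound recording.

    The recording is deterministic for a fixed ``(class_label, duration,
    rate, seed, recipe)``.  Heart rate and murmur amplitude are jittered
    around the recipe values (documented constants ``HEART_RATE_JITTER``,
    ``MURMUR_AMP_JITTER``) so that repeated seeds give distinct but
    class-consistent recordings.
    """
    if class_label not in CLASSES:
        raise ValidationError(
            f"unknown class label {class_label!r}; expected one of {CLASSES}"
        )
    base = recipe if recipe is not None else DEFAULT_RECIPES[class_label]
    rng = np.random.default_rng(seed)

    hr = base.heart_rate * (1.0 + HEART_RATE_JITTER * rng.uniform(-1, 1))
    mamp = base.murmur_amp * (1.0 + MURMUR_AMP_JITTER * rng.uniform(-1, 1))
    rec = replace(base, heart_rate=hr, murmur_amp=mamp)

    cycle = 60.0 / rec.heart_rate
    if duration < cycle:
        raise ValidationError(
            f"duration {duration} s is shorter than one cardiac cycle ({cycle:.2f} s)"
        )
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)

    n_cycles = int(np.ceil(duration / cycle)) + 1
    s1_phase = rng.uniform(0, 2 * np.pi)
    s2_phase = rng.uniform(0, 2 * np.pi)
    for c in range(n_cycles):
        t0 = c * cycle
        x += _tone_burst(t, t0 + rec.s1_dur / 2, rec.s1_dur, rec.s1_freq, 1.0, s1_phase)
        x += _tone_burst(t, t0 + rec.s2_onset_frac * cycle + rec.s2_dur / 2,
                         rec.s2_dur, rec.s2_freq, 0.8, s2_phase)
        if rec.click is not None:
            cf, cfreq = rec.click
            x += _tone_burst(t, t0 + cf * cycle, 0.02, cfreq, 0.6, 0.0)
        if rec.murmur_window is not None and rec.murmur_band is not None:
            lo, hi = rec.murmur_window
            i0 = int(round((t0 + lo * cycle) * rate))
            i1 = int(round((t0 + hi * cycle) * rate))
            i0c, i1c = max(i0, 0), min(i1, n)
            if i1c > i0c:
                noise = _band_noise(i1 - i0, rec.murmur_band, rate, rng)
                u = (np.arange(i0, i1) - i0) / max(i1 - i0 - 1, 1)
                seg = rec.murmur_amp * _envelope(u, rec.murmur_envelope) * noise
                x[i0c:i1c] += seg[i0c - i0:(i1c - i0)]

    peak = np.max(np.abs(x))
    if peak > 0:
        x *= PEAK_LEVEL / peak

    if np.isfinite(rec.noise_snr):
        sig_power = np.mean(x**2)
        noise_power = sig_power / 10 ** (rec.noise_snr / 10)
        x = x + rng.standard_normal(n) * np.sqrt(noise_power)

    peak = np.max(np.abs(x))
    if peak > 1.0:
        x *= 0.99 / peak
    return Signal(x, float(rate), label=class_label)


def synth_dataset(n_per_class: int, duration: float = 3.0, rate: float = 8000.0,
                  seed: int = 0, out_dir: str | Path | None = None,
                  ) -> tuple[list[Signal], list[dict]]:
    """Generate a balanced labeled dataset of 5 * ``n_per_class`` recordings.

    Per-recording seeds are derived deterministically from the master seed,
    so the same call always yields identical audio and manifest.  When
    ``out_dir`` is given, WAV files are written into class-named folders with
    a ``manifest.csv`` alongside.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(5 * n_per_class) % (2**31)
    signals: list[Signal] = []
    manifest: list[dict] = []
    idx = 0
    for label in CLASSES:
        for j in range(n_per_class):
            sig = synth_recording(label, duration, rate, seed=int(seeds[idx]))
            signals.append(sig)
            manifest.append({
                "filename": f"{label}/{label}_{j:04d}.wav",
                "label": label,
                "rate": int(rate),
                "duration": sig.duration,
            })
            idx += 1
    if out_dir is not None:
        out_dir = Path(out_dir)
        for sig, row in zip(signals, manifest):
            path = out_dir / row["filename"]
            path.parent.mkdir(parents=True, exist_ok=True)
            write_wav(path, sig)
        write_manifest(out_dir / "manifest.csv", manifest)
    return signals, manifest
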