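"""Independent naive reference implementations used as test oracles.

Everything here is written from the definitions with explicit loops and
direct (matrix) DFT/DCT sums, deliberately sharing no code with the package
under test.
"""

import math

import numpy as np


# ---------------------------------------------------------------- time domain

def naive_time_domain(x):
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    rms = math.sqrt(sum(v * v for v in x) / n)
    abs_mean = sum(abs(v) for v in x) / n
    peak = max(abs(v) for v in x)
    sqrt_mean = sum(math.sqrt(abs(v)) for v in x) / n
    var_sample = sum((v - mean) ** 2 for v in x) / (n - 1)
    return {
        "rms": rms,
        "shape_factor": rms / abs_mean,
        "skewness": m3 / m2 ** 1.5,
        "kurtosis": m4 / m2 ** 2,
        "peak": peak,
        "impulse_factor": peak / abs_mean,
        "crest_factor": peak / rms,
        "clearance_factor": peak / sqrt_mean ** 2,
        "mean": mean,
        "std": math.sqrt(var_sample),
    }


# ------------------------------------------------------------ spectral quality

def _kaiser_periodic(n, beta):
    # periodic Kaiser window: symmetric window of length n+1, last sample dropped
    m = n  # denominator of the (n+1)-point symmetric window
    k = np.arange(n)
    return np.i0(beta * np.sqrt(1 - (2 * k / m - 1) ** 2)) / np.i0(beta)


def _direct_periodogram(x, fs, beta=38.0):
    n = len(x)
    w = _kaiser_periodic(n, beta)
    x = np.asarray(x, dtype=float)
    xw = (x - x.mean()) * w  # constant detrend before windowing
    grid = np.arange(n)
    dft = np.exp(-2j * np.pi * np.outer(grid[: n // 2 + 1], grid) / n)
    spec = dft @ xw
    scale = 1.0 / (fs * np.sum(w * w))
    pxx = (np.abs(spec) ** 2) * scale
    pxx[1:] *= 2.0
    if n % 2 == 0:
        pxx[-1] /= 2.0
    freqs = np.arange(n // 2 + 1) * fs / n
    return freqs, pxx


def _span(pxx, k):
    lo = k
    while lo > 0 and pxx[lo - 1] < pxx[lo]:
        lo -= 1
    hi = k
    while hi < len(pxx) - 1 and pxx[hi + 1] < pxx[hi]:
        hi += 1
    return lo, hi + 1


def naive_spectral_quality(x, fs, n_harmonics=6):
    freqs, pxx = _direct_periodogram(x, fs)
    used = [False] * len(pxx)
    lo, hi = _span(pxx, 0)
    for i in range(lo, hi):
        used[i] = True
    k_fund, best = -1, -1.0
    for i in range(len(pxx)):
        if not used[i] and pxx[i] > best:
            k_fund, best = i, pxx[i]
    f_lo, f_hi = _span(pxx, k_fund)
    p_fund = float(sum(pxx[f_lo:f_hi]))
    for i in range(f_lo, f_hi):
        used[i] = True
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
        hi = min(k0 + half + 1, len(pxx))
        k_peak, best = lo, pxx[lo]
        for i in range(lo, hi):
            if pxx[i] > best:
                k_peak, best = i, pxx[i]
        h_lo, h_hi = _span(pxx, k_peak)
        for i in range(h_lo, h_hi):
            if not used[i]:
                p_harm += float(pxx[i])
                used[i] = True
    p_noise = float(sum(p for p, u in zip(pxx, used) if not u))
    tiny = np.finfo(float).tiny
    p_noise = max(p_noise, tiny)
    p_harm = max(p_harm, tiny)
    return {
        "snr_db": 10 * math.log10(p_fund / p_noise),
        "sinad_db": 10 * math.log10(p_fund / (p_noise + p_harm)),
        "thd_db": 10 * math.log10(p_harm / p_fund),
    }


# ----------------------------------------------------------------------- MFCC

def naive_mel(f):
    return 2595.0 * math.log10(1.0 + f / 700.0)


def naive_mel_inv(m):
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def naive_mfcc(x, fs, n_coeffs=13, frame_len=0.025, hop=0.010, n_filters=26):
    frame = int(round(frame_len * fs))
    step = int(round(hop * fs))
    n_fft = 1
    while n_fft < frame:
        n_fft *= 2
    win = np.array([0.54 - 0.46 * math.cos(2 * math.pi * k / (frame - 1))
                    for k in range(frame)])
    top = naive_mel(fs / 2.0)
    edges = [naive_mel_inv(top * i / (n_filters + 1)) for i in range(n_filters + 2)]
    n_bins = n_fft // 2 + 1
    bin_freqs = [k * fs / n_fft for k in range(n_bins)]
    fbank = np.zeros((n_filters, n_bins))
    for i in range(n_filters):
        left, center, right = edges[i], edges[i + 1], edges[i + 2]
        for k, f in enumerate(bin_freqs):
            rise = (f - left) / (center - left)
            fall = (right - f) / (right - center)
            fbank[i, k] = max(0.0, min(rise, fall))
    grid = np.arange(n_fft)
    dft = np.exp(-2j * np.pi * np.outer(grid[:n_bins], grid) / n_fft)

    n_frames = 1 + (len(x) - frame) // step
    coeffs = np.zeros((n_frames, n_coeffs))
    for fi in range(n_frames):
        seg = np.zeros(n_fft)
        seg[:frame] = np.asarray(x[fi * step: fi * step + frame]) * win
        power = np.abs(dft @ seg) ** 2
        energies = fbank @ power
        log_e = np.log(np.maximum(energies, np.finfo(float).tiny))
        for k in range(n_coeffs):
            acc = 0.0
            for nn in range(n_filters):
                acc += log_e[nn] * math.cos(math.pi * k * (2 * nn + 1) / (2 * n_filters))
            scale = math.sqrt(1.0 / (4.0 * n_filters)) if k == 0 else math.sqrt(
                1.0 / (2.0 * n_filters))
            coeffs[fi, k] = 2.0 * acc * scale
    return coeffs.mean(axis=0)


# ----------------------------------------------------------------------- WKNN

def naive_wknn_predict(train_X, train_y, query, k, classes):
    """Brute-force 1/d-weighted vote with the documented d=0 and tie rules."""
    dists = []
    for i, row in enumerate(train_X):
        d = math.sqrt(sum((a - b) ** 2 for a, b in zip(row, query)))
        dists.append((d, i))
    dists.sort(key=lambda t: (t[0], t[1]))
    nearest = dists[:k]
    zero = [train_y[i] for d, i in nearest if d == 0]
    if zero:
        counts = {}
        for lab in zero:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        for lab in zero:
            if counts[lab] == best:
                return lab
    weights = {c: 0.0 for c in classes}
    for d, i in nearest:
        weights[train_y[i]] += 1.0 / d
    best = max(weights.values())
    for d, i in nearest:
        if math.isclose(weights[train_y[i]], best):
            return train_y[i]
    raise AssertionError("unreachable")
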