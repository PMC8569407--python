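"""Time- and frequency-domain features of one window's tri-axial acceleration.

The vector has exactly 85 named slots computed from the three axes (x, y, z)
and the total acceleration (per-sample Euclidean norm) treated as a fourth
signal:

time domain (60)
    mean, standard deviation, range of x/y/z/total ............. 12
    pairwise axis correlations xy, xz, yz ......................  3
    kurtosis, skewness, average absolute difference of x/y/z ...  9
    10-bin histogram counts of x/y/z ........................... 30
    mean inter-peak interval + peak count of x/y/z .............  6

frequency domain (25), via FFT of the raw block (no detrend/taper)
    signal energy of x/y/z/total ...............................  4
    mean of the three dominant frequencies of x/y/z/total ......  4
    amplitudes of the three dominant frequencies of x/y/z/total  12
    total spectral power density of x/y/z/total ................  4
    dominant frequency of the total-acceleration signal ........  1

Conventions that the numbers depend on (fixed so independent oracles can
reproduce them):

* standard deviation uses the n-1 denominator; kurtosis is excess kurtosis
  and, like skewness, uses biased moment estimators;
* zero-variance signals map correlation/kurtosis/skewness to 0;
* histogram bins are 10 equal-width bins spanning [min, max] of the axis
  within the window, right-most bin closed; a constant axis puts all samples
  in the first bin;
* a peak is a strict local maximum; peaks closer than 0.2 s are thinned
  keeping the higher one (distance filter first), then peaks with topographic
  prominence below 0.05 g are dropped;
* amplitude spectrum is the one-sided FFT magnitude divided by the sample
  count; dominant frequencies exclude DC and are ordered by descending
  amplitude; signal energy is the mean squared amplitude over positive
  frequencies; total spectral power density is the frequency-integrated
  one-sided periodogram (equal to the mean squared signal by Parseval).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal import find_peaks

PEAK_MIN_SEPARATION_S = 0.2
PEAK_MIN_PROMINENCE_G = 0.05
N_HIST_BINS = 10

AXES = ("x", "y", "z")
SIGNALS = ("x", "y", "z", "total")


def _feature_names() -> list[str]:
    names: list[str] = []
    for fam in ("mean", "sd", "range"):
        names += [f"{fam}_{s}" for s in SIGNALS]
    names += ["corr_xy", "corr_xz", "corr_yz"]
    for fam in ("kurtosis", "skewness", "aad"):
        names += [f"{fam}_{a}" for a in AXES]
    for a in AXES:
        names += [f"hist_{a}_{k}" for k in range(1, N_HIST_BINS + 1)]
    names += [f"peak_interval_{a}" for a in AXES]
    names += [f"peak_count_{a}" for a in AXES]
    for fam in ("energy", "domfreq_mean"):
        names += [f"{fam}_{s}" for s in SIGNALS]
    for s in SIGNALS:
        names += [f"domamp_{s}_{k}" for k in range(1, 4)]
    names += [f"psd_{s}" for s in SIGNALS]
    names += ["domfreq_total"]
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(_feature_names())
assert len(FEATURE_NAMES) == 85


def total_acceleration(acc_block: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(ax^2 + ay^2 + az^2) of an (n, 3) block."""
    block = np.asarray(acc_block, dtype=float)
    if block.ndim != 2 or block.shape[1] != 3 or block.shape[0] == 0:
        raise ValueError("acc_block must be a non-empty (n, 3) array")
    return np.sqrt(np.sum(block * block, axis=1))


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    da, db = a - a.mean(), b - b.mean()
    va, vb = float(da @ da), float(db @ db)
    if va == 0.0 or vb == 0.0:
        return 0.0
    return float(da @ db) / math.sqrt(va * vb)


def _kurtosis(centered: np.ndarray) -> float:
    m2 = float(np.mean(centered**2))
    if m2 == 0:
        return 0.0
    return float(np.mean(centered**4)) / m2**2 - 3.0


def _skewness(centered: np.ndarray) -> float:
    m2 = float(np.mean(centered**2))
    if m2 == 0:
        return 0.0
    return float(np.mean(centered**3)) / m2**1.5


def _histogram(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        counts = np.zeros(N_HIST_BINS)
        counts[0] = x.size
        return counts
    counts, _ = np.histogram(x, bins=N_HIST_BINS, range=(lo, hi))
    return counts.astype(float)


def find_signal_peaks(x: np.ndarray, fs_hz: float) -> np.ndarray:
    """Indices of accepted peaks under the package's peak rule."""
    distance = max(1, int(round(PEAK_MIN_SEPARATION_S * fs_hz)))
    peaks, _ = find_peaks(x, distance=distance, prominence=PEAK_MIN_PROMINENCE_G)
    return peaks


def time_domain_features(acc_block: np.ndarray, fs_hz: float = 50.0) -> dict[str, float]:
    """The 60 time-domain features of an (n, 3) block (n >= 4)."""
    block = np.asarray(acc_block, dtype=float)
    if block.shape[0] < 4:
        raise ValueError("need at least 4 samples for moment features")
    total = total_acceleration(block)
    sigs = {"x": block[:, 0], "y": block[:, 1], "z": block[:, 2], "total": total}

    centered = {s: v - v.mean() for s, v in sigs.items()}

    out: dict[str, float] = {}
    for s, v in sigs.items():
        out[f"mean_{s}"] = float(v.mean())
    n = block.shape[0]
    for s in SIGNALS:
        c = centered[s]
        out[f"sd_{s}"] = math.sqrt(float(c @ c) / (n - 1))
    for s, v in sigs.items():
        out[f"range_{s}"] = float(v.max() - v.min())
    out["corr_xy"] = _corr(sigs["x"], sigs["y"])
    out["corr_xz"] = _corr(sigs["x"], sigs["z"])
    out["corr_yz"] = _corr(sigs["y"], sigs["z"])
    for a in AXES:
        out[f"kurtosis_{a}"] = _kurtosis(centered[a])
    for a in AXES:
        out[f"skewness_{a}"] = _skewness(centered[a])
    for a in AXES:
        out[f"aad_{a}"] = float(np.mean(np.abs(centered[a])))
    for a in AXES:
        for k, c in enumerate(_histogram(sigs[a]), start=1):
            out[f"hist_{a}_{k}"] = float(c)
    for a in AXES:
        peaks = find_signal_peaks(sigs[a], fs_hz)
        if peaks.size >= 2:
            out[f"peak_interval_{a}"] = float(np.mean(np.diff(peaks)) / fs_hz)
        else:
            out[f"peak_interval_{a}"] = 0.0
        out[f"peak_count_{a}"] = float(peaks.size)
    return out


def _spectral(v: np.ndarray, fs_hz: float) -> dict[str, float]:
    n = v.size
    mag = np.abs(rfft(v))
    amp = mag / n
    freqs = rfftfreq(n, d=1.0 / fs_hz)
    pos_amp = amp[1:]
    # one-sided boxcar periodogram integrated over frequency (= mean(v^2))
    pxx = mag**2 / (fs_hz * n)
    if n % 2 == 0:
        pxx[1:-1] *= 2.0
    else:
        pxx[1:] *= 2.0
    df = fs_hz / n
    psd = float(np.sum(pxx) * df)
    if not np.any(pos_amp > 0):
        return {"energy": 0.0, "domfreq_mean": 0.0, "domamps": (0.0, 0.0, 0.0),
                "psd": psd, "domfreq_1": 0.0}
    order = np.argsort(-pos_amp, kind="stable")[:3]
    dom_freqs = freqs[1:][order]
    dom_amps = pos_amp[order]
    return {
        "energy": float(np.mean(pos_amp**2)),
        "domfreq_mean": float(np.mean(dom_freqs)),
        "domamps": tuple(float(a) for a in dom_amps),
        "psd": psd,
        "domfreq_1": float(dom_freqs[0]),
    }


def freq_domain_features(acc_block: np.ndarray, fs_hz: float = 50.0) -> dict[str, float]:
    """The 25 frequency-domain features of an (n, 3) block."""
    block = np.asarray(acc_block, dtype=float)
    total = total_acceleration(block)
    sigs = {"x": block[:, 0], "y": block[:, 1], "z": block[:, 2], "total": total}
    spectra = {s: _spectral(v, fs_hz) for s, v in sigs.items()}

    out: dict[str, float] = {}
    for s in SIGNALS:
        out[f"energy_{s}"] = spectra[s]["energy"]
    for s in SIGNALS:
        out[f"domfreq_mean_{s}"] = spectra[s]["domfreq_mean"]
    for s in SIGNALS:
        for k in range(3):
            out[f"domamp_{s}_{k + 1}"] = spectra[s]["domamps"][k]
    for s in SIGNALS:
        out[f"psd_{s}"] = spectra[s]["psd"]
    out["domfreq_total"] = spectra["total"]["domfreq_1"]
    return out


def acc_feature_vector(acc_block: np.ndarray, fs_hz: float = 50.0) -> dict[str, float]:
    """All 85 features in the FEATURE_NAMES order."""
    feats = time_domain_features(acc_block, fs_hz)
    feats.update(freq_domain_features(acc_block, fs_hz))
    out = {name: feats[name] for name in FEATURE_NAMES}
    if len(out) != 85:
        raise AssertionError("feature inventory drifted from 85 slots")
    return out
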