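"""Independent naive-loop oracles for the windowed features.

Everything here is written with explicit Python loops and textbook formulas
(direct O(n^2) DFT, hand prominence search, scalar haversine variants) so it
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import cmath
import math


def naive_mean(xs):
    return sum(xs) / len(xs)


def naive_sd(xs):
    m = naive_mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def naive_range(xs):
    return max(xs) - min(xs)


def naive_corr(a, b):
    ma, mb = naive_mean(a), naive_mean(b)
    da = [x - ma for x in a]
    db = [x - mb for x in b]
    va = sum(x * x for x in da)
    vb = sum(x * x for x in db)
    if va == 0 or vb == 0:
        return 0.0
    return sum(x * y for x, y in zip(da, db)) / math.sqrt(va * vb)


def naive_moment(xs, k):
    m = naive_mean(xs)
    return sum((x - m) ** k for x in xs) / len(xs)


def naive_kurtosis(xs):
    m2 = naive_moment(xs, 2)
    if m2 == 0:
        return 0.0
    return naive_moment(xs, 4) / m2**2 - 3.0


def naive_skewness(xs):
    m2 = naive_moment(xs, 2)
    if m2 == 0:
        return 0.0
    return naive_moment(xs, 3) / m2**1.5


def naive_aad(xs):
    m = naive_mean(xs)
    return sum(abs(x - m) for x in xs) / len(xs)


def naive_histogram(xs, n_bins=10):
    lo, hi = min(xs), max(xs)
    counts = [0] * n_bins
    if hi == lo:
        counts[0] = len(xs)
        return counts
    width = (hi - lo) / n_bins
    for x in xs:
        k = int((x - lo) / width)
        if k >= n_bins:  # right-most bin closed
            k = n_bins - 1
        counts[k] += 1
    return counts


def naive_prominence(xs, i):
    """Topographic prominence of the peak at index i (signal edges as bases)."""
    left_min = xs[i]
    j = i - 1
    while j >= 0 and xs[j] <= xs[i]:
        left_min = min(left_min, xs[j])
        j -= 1
    right_min = xs[i]
    j = i + 1
    while j < len(xs) and xs[j] <= xs[i]:
        right_min = min(right_min, xs[j])
        j += 1
    return xs[i] - max(left_min, right_min)


def naive_peaks(xs, fs_hz, min_sep_s=0.2, min_prominence=0.05):
    """Strict local maxima, thinned by separation (higher peak wins) and
    then filtered by prominence — the same rule order the package uses."""
    candidates = [
        i for i in range(1, len(xs) - 1) if xs[i - 1] < xs[i] and xs[i] > xs[i + 1]
    ]
    distance = max(1, round(min_sep_s * fs_hz))
    removed = set()
    for i in sorted(candidates, key=lambda i: xs[i], reverse=True):
        if i in removed:
            continue
        for j in candidates:
            if j != i and j not in removed and abs(j - i) < distance:
                removed.add(j)
    kept = [i for i in candidates if i not in removed]
    return [i for i in kept if naive_prominence(xs, i) >= min_prominence]


def naive_peak_features(xs, fs_hz):
    peaks = naive_peaks(xs, fs_hz)
    if len(peaks) >= 2:
        gaps = [(b - a) / fs_hz for a, b in zip(peaks, peaks[1:])]
        interval = sum(gaps) / len(gaps)
    else:
        interval = 0.0
    return interval, float(len(peaks))


def naive_dft_amplitudes(xs):
    """One-sided amplitude spectrum |X_k|/n via the O(n^2) DFT definition."""
    n = len(xs)
    amps = []
    for k in range(n // 2 + 1):
        acc = 0j
        for j, x in enumerate(xs):
            acc += x * cmath.exp(-2j * math.pi * j * k / n)
        amps.append(abs(acc) / n)
    return amps


def naive_spectral(xs, fs_hz):
    """energy, mean/amps of top-3 dominant frequencies, psd, dominant freq."""
    n = len(xs)
    amps = naive_dft_amplitudes(xs)
    freqs = [k * fs_hz / n for k in range(len(amps))]
    pos = list(range(1, len(amps)))
    if all(amps[k] == 0 for k in pos):
        return {"energy": 0.0, "domfreq_mean": 0.0, "domamps": [0.0] * 3,
                "psd": naive_mean([x * x for x in xs]), "domfreq_1": 0.0}
    order = sorted(pos, key=lambda k: (-amps[k], k))[:3]
    energy = sum(amps[k] ** 2 for k in pos) / len(pos)
    # integrated one-sided periodogram equals the mean square (Parseval)
    psd = naive_mean([x * x for x in xs])
    return {
        "energy": energy,
        "domfreq_mean": sum(freqs[k] for k in order) / 3,
        "domamps": [amps[k] for k in order],
        "psd": psd,
        "domfreq_1": freqs[order[0]],
    }


def naive_feature_dict(block, fs_hz=50.0):
    """All 85 features of an (n, 3) block, brute force."""
    xs = [row[0] for row in block]
    ys = [row[1] for row in block]
    zs = [row[2] for row in block]
    tot = [math.sqrt(x * x + y * y + z * z) for x, y, z in zip(xs, ys, zs)]
    sigs = {"x": xs, "y": ys, "z": zs, "total": tot}
    out = {}
    for s, v in sigs.items():
        out[f"mean_{s}"] = naive_mean(v)
        out[f"sd_{s}"] = naive_sd(v)
        out[f"range_{s}"] = naive_range(v)
    out["corr_xy"] = naive_corr(xs, ys)
    out["corr_xz"] = naive_corr(xs, zs)
    out["corr_yz"] = naive_corr(ys, zs)
    for a, v in (("x", xs), ("y", ys), ("z", zs)):
        out[f"kurtosis_{a}"] = naive_kurtosis(v)
        out[f"skewness_{a}"] = naive_skewness(v)
        out[f"aad_{a}"] = naive_aad(v)
        for k, c in enumerate(naive_histogram(v), start=1):
            out[f"hist_{a}_{k}"] = float(c)
        interval, count = naive_peak_features(v, fs_hz)
        out[f"peak_interval_{a}"] = interval
        out[f"peak_count_{a}"] = count
    for s, v in sigs.items():
        spec = naive_spectral(v, fs_hz)
        out[f"energy_{s}"] = spec["energy"]
        out[f"domfreq_mean_{s}"] = spec["domfreq_mean"]
        for k in range(3):
            out[f"domamp_{s}_{k + 1}"] = spec["domamps"][k]
        out[f"psd_{s}"] = spec["psd"]
    out["domfreq_total"] = naive_spectral(tot, fs_hz)["domfreq_1"]
    return out


def naive_haversine(lat1, lon1, lat2, lon2, radius=6_371_000.0):
    """Great-circle distance via the atan2 form (different from the asin form)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    y = math.sqrt(
        (math.cos(p2) * math.sin(dl)) ** 2
        + (math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dl)) ** 2
    )
    x = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius * math.atan2(y, x)
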