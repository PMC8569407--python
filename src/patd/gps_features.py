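"""Per-window GPS features: average speed and signed elevation difference.

Speed is path length over elapsed time using great-circle (haversine)
distances between consecutive fixes; elevation difference is last minus
first fix (signed, so uphill and downhill keep their direction).  A window
with fewer than two fixes cannot yield either feature and is flagged
invalid; downstream, GPS-augmented feature tables drop such windows while
accelerometer-only tables keep them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

GPS_FEATURE_NAMES = ("gps_avg_speed", "gps_elev_diff")


@dataclass(frozen=True)
class GpsFeaturePair:
    avg_speed: float  # m/s
    elev_diff: float  # m, signed
    n_fixes: int
    valid: bool


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in meters on a sphere of radius 6371 km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


def window_gps_features(gps_fixes: np.ndarray) -> GpsFeaturePair:
    """Features of the (n, 4) fix array [t, lat, lon, elev] of one window.

    avg_speed = total haversine path length / (t_last - t_first);
    elev_diff = elev_last - elev_first.  Fixes must be strictly
    time-ordered; fewer than two fixes gives an invalid pair.
    """
    fixes = np.asarray(gps_fixes, dtype=float)
    n = fixes.shape[0]
    if n < 2:
        return GpsFeaturePair(math.nan, math.nan, n, False)
    t = fixes[:, 0]
    if np.any(np.diff(t) <= 0):
        raise ValueError("gps fixes must be strictly increasing in time")
    dist = sum(
        haversine_m(fixes[i, 1], fixes[i, 2], fixes[i + 1, 1], fixes[i + 1, 2])
        for i in range(n - 1)
    )
    elapsed = t[-1] - t[0]
    return GpsFeaturePair(
        avg_speed=float(dist / elapsed),
        elev_diff=float(fixes[-1, 3] - fixes[0, 3]),
        n_fixes=n,
        valid=True,
    )
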