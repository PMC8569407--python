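"""Cut streams into overlapping fixed-length windows and label each one.

Windows are half-open intervals [t0 + k*step, t0 + k*step + window_len) laid
on the accelerometer clock.  A window is kept only when it holds at least
``min_fill_frac`` of the nominal sample count (dropouts suppress windows
rather than being interpolated) and when a single activity covers at least
``purity_min`` of its duration (transition windows are discarded so the
classification problem stays single-label).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sensor_io import LabelTrack, SubjectRecord

_EPS = 1e-9


@dataclass(frozen=True)
class SegmentationConfig:
    window_len_s: float = 2.0
    step_s: float = 1.0
    purity_min: float = 0.8
    min_fill_frac: float = 0.8
    fs_nominal_hz: float = 50.0

    def __post_init__(self) -> None:
        if self.window_len_s <= 0:
            raise ValueError("window_len_s must be > 0")
        if not 0 < self.step_s <= self.window_len_s:
            raise ValueError("step_s must be in (0, window_len_s]")
        if not 0.5 < self.purity_min <= 1.0:
            raise ValueError("purity_min must be in (0.5, 1]")


@dataclass
class Window:
    """One labeled slice of a single placement's stream."""

    subject_id: str
    cohort: str
    position: str
    t_start: float
    duration: float
    acc_block: np.ndarray  # (n, 3) of ax, ay, az
    acc_t: np.ndarray
    gps_fixes: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))  # t,lat,lon,elev
    label: str | None = None
    protocol: str | None = None


def segment(
    record: SubjectRecord,
    position: str,
    config: SegmentationConfig = SegmentationConfig(),
) -> list[Window]:
    """Windows of one placement's stream, labeled from the record's track.

    Candidate starts run from the stream's first timestamp in ``step_s``
    increments as long as a full window fits within the recording span; the
    fill rule then drops windows over dropouts.  An empty stream yields an
    empty list.
    """
    stream = record.acc[position]
    if stream.t.size == 0:
        return []
    windows = []
    t0 = float(stream.t[0])
    span_end = float(stream.t[-1]) + 1.0 / config.fs_nominal_hz
    n_nominal = config.window_len_s * config.fs_nominal_hz
    min_count = config.min_fill_frac * n_nominal

    gps = record.gps
    k = 0
    while t0 + k * config.step_s + config.window_len_s <= span_end + _EPS:
        ws = t0 + k * config.step_s
        we = ws + config.window_len_s
        k += 1
        i0, i1 = np.searchsorted(stream.t, [ws - _EPS, we - _EPS])
        if i1 - i0 < min_count:
            continue
        block = np.column_stack([stream.ax[i0:i1], stream.ay[i0:i1], stream.az[i0:i1]])
        if gps is not None:
            g0, g1 = np.searchsorted(gps.t, [ws - _EPS, we - _EPS])
            fixes = np.column_stack([gps.t[g0:g1], gps.lat[g0:g1], gps.lon[g0:g1], gps.elev[g0:g1]])
        else:
            fixes = np.empty((0, 4))
        label, protocol = assign_label(ws, we, record.labels, config.purity_min)
        windows.append(
            Window(
                subject_id=record.subject_id,
                cohort=record.cohort,
                position=position,
                t_start=ws,
                duration=config.window_len_s,
                acc_block=block,
                acc_t=stream.t[i0:i1].copy(),
                gps_fixes=fixes,
                label=label,
                protocol=protocol,
            )
        )
    return windows


def assign_label(
    t_start: float,
    t_end: float,
    track: LabelTrack,
    purity_min: float,
) -> tuple[str | None, str | None]:
    """Dominant (activity, protocol) of a window, or (None, None).

    The activity covering the largest share of the window wins iff that share
    is at least ``purity_min`` of the window duration; the protocol is taken
    from the same covering intervals.  Order-independent with respect to the
    interval listing.
    """
    if not 0.5 < purity_min <= 1.0:
        raise ValueError("purity_min must be in (0.5, 1]")
    duration = t_end - t_start
    coverage: dict[tuple[str, str], float] = {}
    for iv_start, iv_end, activity, protocol in track.intervals:
        overlap = min(t_end, iv_end) - max(t_start, iv_start)
        if overlap > 0:
            key = (activity, protocol)
            coverage[key] = coverage.get(key, 0.0) + overlap
    if not coverage:
        return None, None
    # deterministic tie-break: larger coverage, then lexicographic key
    (activity, protocol), best = max(coverage.items(), key=lambda kv: (kv[1], kv[0]))
    if best / duration + _EPS >= purity_min:
        return activity, protocol
    return None, None
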