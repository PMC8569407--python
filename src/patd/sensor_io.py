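"""On-disk data model for raw wearable streams and activity labels.

One directory per subject:

    <subject_id>/
        meta.json           subject_id, cohort, acc_units ("g")
        acc_<position>.csv  columns t,ax,ay,az      (nominal 50 Hz)
        gps.csv             columns t,lat,lon,elev  (nominal 1 Hz, optional)
        labels.csv          columns t_start,t_end,activity,protocol

Timestamps are seconds from session start.  Acceleration is in units of g so
that resting postures have |a| near 1.  Floats are written with ``repr`` so a
round trip reproduces every value bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ACTIVITIES, COHORTS, POSITIONS, PROTOCOLS

NOMINAL_ACC_DT_S = 0.02  # 50 Hz

ACC_COLUMNS = ["t", "ax", "ay", "az"]
GPS_COLUMNS = ["t", "lat", "lon", "elev"]
LABEL_COLUMNS = ["t_start", "t_end", "activity", "protocol"]


class SchemaError(ValueError):
    """A stream file does not conform to the expected schema."""


class ValidationError(ValueError):
    """A stream violates a domain invariant (with row-level diagnostics)."""


class SensorDataWarning(UserWarning):
    """Non-fatal data-quality issue (duplicate timestamps, odd sampling rate)."""


@dataclass
class AccStream:
    """Tri-axial acceleration samples for one device placement."""

    subject_id: str
    position: str
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValidationError(f"unknown position {self.position!r}")
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        _check_acc(self)

    def samples(self) -> np.ndarray:
        """Return an (n, 3) array of [ax, ay, az]."""
        return np.column_stack([self.ax, self.ay, self.az])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AccStream)
            and self.subject_id == other.subject_id
            and self.position == other.position
            and all(
                np.array_equal(getattr(self, f), getattr(other, f))
                for f in ("t", "ax", "ay", "az")
            )
        )


@dataclass
class GpsStream:
    """1 Hz GPS fixes; gaps are permitted and preserved verbatim."""

    subject_id: str
    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    elev: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.elev = np.asarray(self.elev, dtype=float)
        bad_lat = np.flatnonzero((self.lat < -90) | (self.lat > 90))
        if bad_lat.size:
            raise ValidationError(f"gps lat out of [-90, 90] at rows {bad_lat[:10].tolist()}")
        bad_lon = np.flatnonzero((self.lon < -180) | (self.lon > 180))
        if bad_lon.size:
            raise ValidationError(f"gps lon out of [-180, 180] at rows {bad_lon[:10].tolist()}")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            rows = np.flatnonzero(np.diff(self.t) <= 0)
            raise ValidationError(f"gps t not strictly increasing at rows {rows[:10].tolist()}")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GpsStream)
            and self.subject_id == other.subject_id
            and all(
                np.array_equal(getattr(self, f), getattr(other, f))
                for f in ("t", "lat", "lon", "elev")
            )
        )


@dataclass
class LabelTrack:
    """Non-overlapping labeled activity intervals tagged with protocol."""

    subject_id: str
    intervals: list[tuple[float, float, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, (t0, t1, act, proto) in enumerate(self.intervals):
            if not t0 < t1:
                raise ValidationError(f"label row {i}: t_start {t0} >= t_end {t1}")
            if act not in ACTIVITIES:
                raise ValidationError(f"label row {i}: unknown activity {act!r}")
            if proto not in PROTOCOLS:
                raise ValidationError(f"label row {i}: unknown protocol {proto!r}")
        ordered = sorted(self.intervals, key=lambda iv: iv[0])
        for (_, end_a, _, _), (start_b, _, _, _) in zip(ordered, ordered[1:]):
            if start_b < end_a - 1e-9:
                raise ValidationError(
                    f"overlapping label intervals near t={start_b:g}"
                )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LabelTrack)
            and self.subject_id == other.subject_id
            and self.intervals == other.intervals
        )


@dataclass(eq=True)
class SubjectRecord:
    """All streams of one participant plus cohort membership."""

    subject_id: str
    cohort: str
    acc: dict[str, AccStream]
    gps: GpsStream | None
    labels: LabelTrack

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(f"unknown cohort {self.cohort!r}")
        if not self.acc:
            raise ValidationError("at least one accelerometer position required")
        for pos, stream in self.acc.items():
            if stream.position != pos:
                raise ValidationError(f"acc map key {pos!r} != stream position {stream.position!r}")
            if stream.subject_id != self.subject_id:
                raise ValidationError("acc stream subject_id mismatch")
        if self.gps is not None and self.gps.subject_id != self.subject_id:
            raise ValidationError("gps stream subject_id mismatch")
        if self.labels.subject_id != self.subject_id:
            raise ValidationError("label track subject_id mismatch")


def _check_acc(stream: AccStream) -> None:
    t = stream.t
    for name in ("ax", "ay", "az"):
        vals = getattr(stream, name)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ValidationError(
                f"{stream.position}: non-finite {name} at rows {bad[:10].tolist()}"
            )
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt < 0):
            rows = np.flatnonzero(dt < 0)
            raise ValidationError(
                f"{stream.position}: t decreasing at rows {rows[:10].tolist()}"
            )
        dup = np.flatnonzero(dt == 0)
        if dup.size:
            # keep-first deduplication, deterministic
            warnings.warn(
                f"{stream.position}: {dup.size} duplicate timestamps dropped (kept first)",
                SensorDataWarning,
                stacklevel=3,
            )
            keep = np.concatenate([[True], dt > 0])
            stream.t = t[keep]
            stream.ax = stream.ax[keep]
            stream.ay = stream.ay[keep]
            stream.az = stream.az[keep]
        med = float(np.median(np.diff(stream.t))) if stream.t.size > 1 else NOMINAL_ACC_DT_S
        if not (0.9 * NOMINAL_ACC_DT_S <= med <= 1.1 * NOMINAL_ACC_DT_S):
            warnings.warn(
                f"{stream.position}: median sampling interval {med:.4f}s deviates "
                f"from nominal {NOMINAL_ACC_DT_S}s by more than 10%",
                SensorDataWarning,
                stacklevel=3,
            )


def _fmt(x: float) -> str:
    return repr(float(x))


def _write_csv(path: Path, header: list[str], rows) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(row) + "\n")


def _read_csv(path: Path, expected: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != expected:
        raise SchemaError(
            f"{path.name}: expected columns {expected}, found {list(df.columns)}"
        )
    return df


def write_subject(record: SubjectRecord, dir_path: str | Path) -> Path:
    """Write one subject directory; returns its path.

    Files are byte-stable: floats use shortest round-trip representation and
    rows follow stream order, so identical records produce identical bytes.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"subject_id": record.subject_id, "cohort": record.cohort, "acc_units": "g"}
    with open(out / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for pos, stream in sorted(record.acc.items()):
        _write_csv(
            out / f"acc_{pos}.csv",
            ACC_COLUMNS,
            (
                (_fmt(t), _fmt(x), _fmt(y), _fmt(z))
                for t, x, y, z in zip(stream.t, stream.ax, stream.ay, stream.az)
            ),
        )
    if record.gps is not None:
        g = record.gps
        _write_csv(
            out / "gps.csv",
            GPS_COLUMNS,
            (
                (_fmt(t), _fmt(la), _fmt(lo), _fmt(el))
                for t, la, lo, el in zip(g.t, g.lat, g.lon, g.elev)
            ),
        )
    _write_csv(
        out / "labels.csv",
        LABEL_COLUMNS,
        (
            (_fmt(t0), _fmt(t1), act, proto)
            for t0, t1, act, proto in record.labels.intervals
        ),
    )
    return out


def read_subject(dir_path: str | Path) -> SubjectRecord:
    """Read and validate one subject directory.

    A missing ``labels.csv`` or ``meta.json`` is a hard error; a missing
    ``gps.csv`` yields a record with ``gps=None`` so accelerometer-only
    analyses remain possible.
    """
    d = Path(dir_path)
    meta_path = d / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing meta.json in {d}")
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    subject_id = str(meta["subject_id"])
    cohort = str(meta["cohort"])

    label_path = d / "labels.csv"
    if not label_path.exists():
        raise FileNotFoundError(f"missing labels.csv in {d}")
    ldf = _read_csv(label_path, LABEL_COLUMNS)
    labels = LabelTrack(
        subject_id,
        [
            (float(r.t_start), float(r.t_end), str(r.activity), str(r.protocol))
            for r in ldf.itertuples()
        ],
    )

    acc: dict[str, AccStream] = {}
    for pos in POSITIONS:
        path = d / f"acc_{pos}.csv"
        if not path.exists():
            continue
        df = _read_csv(path, ACC_COLUMNS)
        acc[pos] = AccStream(
            subject_id,
            pos,
            df["t"].to_numpy(),
            df["ax"].to_numpy(),
            df["ay"].to_numpy(),
            df["az"].to_numpy(),
        )
    if not acc:
        raise FileNotFoundError(f"no acc_<position>.csv files in {d}")

    gps = None
    gps_path = d / "gps.csv"
    if gps_path.exists():
        gdf = _read_csv(gps_path, GPS_COLUMNS)
        gps = GpsStream(
            subject_id,
            gdf["t"].to_numpy(),
            gdf["lat"].to_numpy(),
            gdf["lon"].to_numpy(),
            gdf["elev"].to_numpy(),
        )

    return SubjectRecord(subject_id, cohort, acc, gps, labels)


def write_cohort(records: list[SubjectRecord], root: str | Path) -> list[Path]:
    """Write one directory per subject under ``root``."""
    return [write_subject(r, Path(root) / r.subject_id) for r in records]


def read_cohort(root: str | Path) -> list[SubjectRecord]:
    """Read every subject directory under ``root`` (sorted by name)."""
    root = Path(root)
    dirs = sorted(p for p in root.iterdir() if (p / "meta.json").exists())
    return [read_subject(p) for p in dirs]
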