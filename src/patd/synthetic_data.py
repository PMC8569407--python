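"""Synthetic two-cohort, five-placement, two-protocol wearable datasets.

The generator emulates the structure of an outdoor activity-recognition
study: each synthetic subject wears five devices (chest, both hips, left
pocket, right knee) recording 50 Hz tri-axial acceleration in units of g,
carries a 1 Hz GPS receiver, and performs a scripted (semi-structured) and a
free-form (real-life) session covering six activities.

The signal model is deliberately simple but captures the contrasts the
pipeline is meant to detect:

* postures (lying / sitting / standing) are a placement-rotated gravity
  vector plus Gaussian noise — distinct mean orientations, no periodicity;
* locomotion (walking / non-level walking / running) adds a harmonic series
  at a subject- and block-specific fundamental along the vertical axis plus
  lateral sway, so the dominant frequency and amplitude features carry the
  class signal;
* the old cohort runs slower and at a step frequency and amplitude much
  closer to its walking gait than the young cohort's, so running/walking
  separation is intrinsically harder for old subjects;
* non-level walking is nearly indistinguishable from level walking in the
  accelerometer channel; it differs chiefly through the GPS elevation trend
  (speed x grade), which is what makes the GPS features informative;
* real-life sessions inflate all parameter variances, more strongly for the
  young cohort (who chose their own environments);
* the knee placement amplifies the periodic leg motion (highest dynamic
  gain) while the pocket placement suffers a random per-session device
  rotation, mimicking loose pockets.

All numeric defaults are package constants chosen to satisfy these
qualitative contrasts; none are measurements.  Generation is fully
deterministic for a given seed (NumPy PCG64 via ``default_rng``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import ACTIVITIES, POSITIONS, POSTURES, PROTOCOLS
from .sensor_io import AccStream, GpsStream, LabelTrack, SubjectRecord

FS_ACC_HZ = 50.0
FS_GPS_HZ = 1.0
GPS_HORIZ_NOISE_M = 0.1
GPS_ELEV_NOISE_M = 0.02
REF_LAT_DEG = 47.40
REF_LON_DEG = 8.55
REF_ELEV_M = 420.0
METERS_PER_DEG_LAT = 6_371_000.0 * math.pi / 180.0
SESSION_GAP_S = 10.0
POCKET_MAX_ROTATION_DEG = 30.0
# gait and pace drift within an activity bout: parameters are redrawn every
# PARAM_REFRESH_S seconds so no block is a single memorizable tone
PARAM_REFRESH_S = 10.0

# placement transform: fixed mounting rotation + gain on the dynamic
# (non-gravity) component.  The knee sees the leg's periodic motion best;
# the chest is furthest from it.
PLACEMENT_ROTATIONS: dict[str, Rotation] = {
    "chest": Rotation.from_euler("y", 15, degrees=True),
    "left_hip": Rotation.from_euler("zx", [90, 10], degrees=True),
    "right_hip": Rotation.from_euler("zx", [-90, -10], degrees=True),
    "left_pocket": Rotation.from_euler("zy", [80, 20], degrees=True),
    "right_knee": Rotation.from_euler("x", 25, degrees=True),
}
PLACEMENT_DYNAMIC_GAIN: dict[str, float] = {
    "chest": 0.55,
    "left_hip": 0.8,
    "right_hip": 0.8,
    "left_pocket": 0.9,
    "right_knee": 1.5,
}
# ground-impact (heel-strike) transients attenuate as they travel up the
# body: the knee sees them nearly unfiltered, the chest barely at all
PLACEMENT_IMPACT_GAIN: dict[str, float] = {
    "chest": 0.1,
    "left_hip": 0.2,
    "right_hip": 0.2,
    "left_pocket": 0.3,
    "right_knee": 1.0,
}
IMPACT_PULSE_WIDTH_S = 0.05


@dataclass(frozen=True)
class ActivitySignalModel:
    """Generative parameters of one activity for one cohort."""

    activity: str
    gravity_orientation: tuple[float, float, float]
    fundamental_freq_hz: tuple[float, float] | None  # (mean, sd); None = posture
    harmonic_amps: tuple[float, ...]  # g, decreasing
    noise_sd: float  # g
    gps_speed_mps: tuple[float, float]  # (mean, sd)
    gps_grade: tuple[float, float] | None = None  # rise/run; non-level only
    impact_amp_g: float = 0.0  # heel-strike pulse height before placement gain

    def __post_init__(self) -> None:
        if self.activity in POSTURES:
            if self.fundamental_freq_hz is not None:
                raise ValueError("posture models have no fundamental frequency")
        else:
            if self.fundamental_freq_hz is None or self.fundamental_freq_hz[0] <= 0:
                raise ValueError("locomotion needs a positive fundamental frequency")
        if self.gps_speed_mps[0] < 0:
            raise ValueError("speeds must be >= 0")


@dataclass(frozen=True)
class SubjectJitter:
    """Per-subject spread of the cohort-level parameters."""

    freq_sd_hz: float = 0.15
    speed_sd_mps: float = 0.10
    amp_frac_sd: float = 0.12
    posture_tilt_deg: float = 3.0


@dataclass(frozen=True)
class CohortProfile:
    cohort: str
    models: dict[str, ActivitySignalModel]
    real_life_variance_inflation: float
    subject_jitter: SubjectJitter = field(default_factory=SubjectJitter)

    def __post_init__(self) -> None:
        missing = set(ACTIVITIES) - set(self.models)
        if missing:
            raise ValueError(f"profile missing activities: {sorted(missing)}")


# default per-protocol schedules; every activity appears in both
DEFAULT_SCHEDULES: dict[str, tuple[tuple[str, float], ...]] = {
    "semi_structured": (
        ("standing", 20.0),
        ("lying", 20.0),
        ("sitting", 20.0),
        ("walking", 40.0),
        ("nonlevel_walking", 30.0),
        ("running", 25.0),
    ),
    "real_life": (
        ("sitting", 25.0),
        ("walking", 30.0),
        ("standing", 15.0),
        ("nonlevel_walking", 25.0),
        ("running", 20.0),
        ("lying", 15.0),
    ),
}

_UP = (0.0, 0.0, 1.0)
_RECLINED = (0.0, 0.5, 0.8660254037844387)
_PRONE = (1.0, 0.0, 0.0)


def default_profiles() -> tuple[CohortProfile, CohortProfile]:
    """The package's default (young, old) cohort profiles.

    The old cohort's running fundamental frequency, amplitude and speed sit
    much closer to its walking gait than the young cohort's do, and the young
    cohort's real-life variance inflation is larger.
    """
    young = CohortProfile(
        cohort="young",
        real_life_variance_inflation=2.0,
        models={
            "lying": ActivitySignalModel("lying", _PRONE, None, (), 0.02, (0.0, 0.0)),
            "sitting": ActivitySignalModel("sitting", _RECLINED, None, (), 0.03, (0.0, 0.0)),
            "standing": ActivitySignalModel("standing", _UP, None, (), 0.03, (0.0, 0.0)),
            "walking": ActivitySignalModel(
                "walking", _UP, (1.90, 0.10), (0.35, 0.12, 0.04), 0.05, (1.40, 0.10),
                impact_amp_g=0.06,
            ),
            "nonlevel_walking": ActivitySignalModel(
                "nonlevel_walking", _UP, (1.88, 0.10), (0.35, 0.12, 0.04), 0.05,
                (1.15, 0.10), gps_grade=(0.12, 0.02), impact_amp_g=0.06,
            ),
            "running": ActivitySignalModel(
                "running", _UP, (2.90, 0.12), (0.90, 0.30, 0.10), 0.08, (3.00, 0.20),
                impact_amp_g=0.45,
            ),
        },
    )
    old = CohortProfile(
        cohort="old",
        real_life_variance_inflation=1.2,
        models={
            "lying": ActivitySignalModel("lying", _PRONE, None, (), 0.02, (0.0, 0.0)),
            "sitting": ActivitySignalModel("sitting", _RECLINED, None, (), 0.03, (0.0, 0.0)),
            "standing": ActivitySignalModel("standing", _UP, None, (), 0.03, (0.0, 0.0)),
            "walking": ActivitySignalModel(
                "walking", _UP, (1.70, 0.10), (0.30, 0.10, 0.035), 0.05, (1.20, 0.10),
                impact_amp_g=0.06,
            ),
            "nonlevel_walking": ActivitySignalModel(
                "nonlevel_walking", _UP, (1.68, 0.10), (0.30, 0.10, 0.035), 0.05,
                (1.00, 0.08), gps_grade=(0.10, 0.02), impact_amp_g=0.06,
            ),
            "running": ActivitySignalModel(
                "running", _UP, (1.90, 0.12), (0.36, 0.13, 0.045), 0.055, (1.80, 0.15),
                impact_amp_g=0.35,
            ),
        },
    )
    return young, old


def distribution_overlap(m1: float, s1: float, m2: float, s2: float) -> float:
    """Overlap coefficient of two normal densities (numeric integral of the min)."""
    lo = min(m1 - 6 * s1, m2 - 6 * s2)
    hi = max(m1 + 6 * s1, m2 + 6 * s2)
    x = np.linspace(lo, hi, 4001)
    p = np.exp(-0.5 * ((x - m1) / s1) ** 2) / (s1 * math.sqrt(2 * math.pi))
    q = np.exp(-0.5 * ((x - m2) / s2) ** 2) / (s2 * math.sqrt(2 * math.pi))
    return float(np.trapezoid(np.minimum(p, q), x))


def running_walking_overlap(profile: CohortProfile) -> float:
    """How much a cohort's running gait overlaps its walking gait (freq x speed)."""
    run, walk = profile.models["running"], profile.models["walking"]
    f = distribution_overlap(*run.fundamental_freq_hz, *walk.fundamental_freq_hz)
    s = distribution_overlap(*run.gps_speed_mps, *walk.gps_speed_mps)
    return 0.5 * (f + s)


@dataclass
class _BlockParams:
    gravity: np.ndarray
    freq_hz: float | None
    amps: np.ndarray
    phases: np.ndarray
    lat_phase: float
    noise_sd: float
    speed_mps: float
    grade: float
    heading_rad: float
    impact_amp: float = 0.0
    impact_phase: float = 0.0


def _draw_block_params(
    model: ActivitySignalModel,
    rng: np.random.Generator,
    inflation: float = 1.0,
    freq_offset: float = 0.0,
    speed_offset: float = 0.0,
    amp_scale: float = 1.0,
    gravity: np.ndarray | None = None,
) -> _BlockParams:
    sd_scale = math.sqrt(inflation)
    if model.fundamental_freq_hz is not None:
        mu, sd = model.fundamental_freq_hz
        freq = max(0.3, mu + freq_offset + rng.normal(0.0, sd * sd_scale))
    else:
        freq = None
    amps = np.asarray(model.harmonic_amps, dtype=float) * amp_scale
    mu_s, sd_s = model.gps_speed_mps
    speed = max(0.0, mu_s + (speed_offset if mu_s > 0 else 0.0) + rng.normal(0.0, sd_s * sd_scale))
    if model.gps_grade is not None:
        g_mu, g_sd = model.gps_grade
        grade = max(0.01, g_mu + rng.normal(0.0, g_sd * sd_scale))
        grade *= rng.choice([-1.0, 1.0])
    else:
        grade = 0.0
    return _BlockParams(
        gravity=np.asarray(gravity if gravity is not None else model.gravity_orientation, float),
        freq_hz=freq,
        amps=amps,
        phases=rng.uniform(0, 2 * math.pi, size=len(model.harmonic_amps)),
        lat_phase=float(rng.uniform(0, 2 * math.pi)),
        noise_sd=model.noise_sd * sd_scale,
        speed_mps=speed,
        grade=grade,
        heading_rad=float(rng.uniform(0, 2 * math.pi)),
        impact_amp=max(0.0, model.impact_amp_g * amp_scale * rng.normal(1.0, 0.12)),
        impact_phase=float(rng.uniform(0, 1.0)),
    )


def _orthogonal_unit(v: np.ndarray) -> np.ndarray:
    e = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    o = e - np.dot(e, v) * v
    return o / np.linalg.norm(o)


def _synth_body_components(
    params: _BlockParams, duration_s: float, fs: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free body-frame signal split into (gravity, harmonics, impacts).

    Harmonics bob along the gravity axis with lateral sway; impacts are a
    train of narrow Gaussian pulses at the gait cycle rate, standing in for
    heel-strike shocks.
    """
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    gravity_part = np.outer(np.ones(n), params.gravity)
    dyn = np.zeros((n, 3))
    impact = np.zeros((n, 3))
    if params.freq_hz is not None and params.amps.size:
        vert = np.zeros(n)
        for k, (amp, ph) in enumerate(zip(params.amps, params.phases), start=1):
            vert += amp * np.sin(2 * math.pi * k * params.freq_hz * t + ph)
        lateral = 0.4 * params.amps[0] * np.sin(2 * math.pi * params.freq_hz * t + params.lat_phase)
        dyn += np.outer(vert, params.gravity)
        dyn += np.outer(lateral, _orthogonal_unit(params.gravity))
        if params.impact_amp > 0:
            period = 1.0 / params.freq_hz
            # distance of each sample to the nearest pulse center
            offset = (t + params.impact_phase * period + 0.5 * period) % period - 0.5 * period
            pulses = params.impact_amp * np.exp(-0.5 * (offset / IMPACT_PULSE_WIDTH_S) ** 2)
            impact += np.outer(pulses, params.gravity)
    return gravity_part, dyn, impact


def _apply_placement(
    gravity_part: np.ndarray,
    body_dyn: np.ndarray,
    body_impact: np.ndarray,
    placement: str,
    extra_rotation: Rotation | None,
) -> np.ndarray:
    gain = PLACEMENT_DYNAMIC_GAIN[placement]
    impact_gain = PLACEMENT_IMPACT_GAIN[placement]
    rot = PLACEMENT_ROTATIONS[placement]
    if extra_rotation is not None:
        rot = extra_rotation * rot
    return rot.apply(gravity_part + gain * body_dyn + impact_gain * body_impact)


def _synth_gps(
    params: _BlockParams,
    duration_s: float,
    fs_gps: float,
    start_enu: np.ndarray,
    t0: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GPS fixes for one block: times, ENU positions (clean end state), noisy fixes."""
    n = int(round(duration_s * fs_gps))
    t = t0 + np.arange(n) / fs_gps
    dt = np.arange(n) / fs_gps
    east = start_enu[0] + params.speed_mps * math.sin(params.heading_rad) * dt
    north = start_enu[1] + params.speed_mps * math.cos(params.heading_rad) * dt
    elev = start_enu[2] + params.speed_mps * params.grade * dt
    fixes = np.column_stack([
        east + rng.normal(0, GPS_HORIZ_NOISE_M, n),
        north + rng.normal(0, GPS_HORIZ_NOISE_M, n),
        elev + rng.normal(0, GPS_ELEV_NOISE_M, n),
    ])
    end = np.array([
        start_enu[0] + params.speed_mps * math.sin(params.heading_rad) * duration_s,
        start_enu[1] + params.speed_mps * math.cos(params.heading_rad) * duration_s,
        start_enu[2] + params.speed_mps * params.grade * duration_s,
    ])
    return t, end, fixes


def enu_to_lat_lon_elev(enu: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local-planar east/north/up meters -> (lat, lon, elev) at the reference point."""
    lat = REF_LAT_DEG + enu[:, 1] / METERS_PER_DEG_LAT
    lon = REF_LON_DEG + enu[:, 0] / (METERS_PER_DEG_LAT * math.cos(math.radians(REF_LAT_DEG)))
    elev = REF_ELEV_M + enu[:, 2]
    return lat, lon, elev


def generate_block(
    model: ActivitySignalModel,
    placement: str,
    duration_s: float,
    fs_acc: float = FS_ACC_HZ,
    fs_gps: float = FS_GPS_HZ,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One standalone activity block for one placement.

    Returns ``(acc, gps)`` where ``acc`` is (n, 4) columns t, ax, ay, az and
    ``gps`` is (m, 4) columns t, lat, lon, elev starting at the reference
    point.  The pocket placement gets a random extra rotation within 30
    degrees of identity, emulating loose-pocket device orientation.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng() if rng is None else rng
    params = _draw_block_params(model, rng)
    gravity_part, dyn, impact = _synth_body_components(params, duration_s, fs_acc)
    extra = _pocket_rotation(rng) if placement == "left_pocket" else None
    acc = _apply_placement(gravity_part, dyn, impact, placement, extra)
    acc = acc + rng.normal(0, params.noise_sd, acc.shape)
    t_acc = np.arange(acc.shape[0]) / fs_acc
    t_gps, _, enu = _synth_gps(params, duration_s, fs_gps, np.zeros(3), 0.0, rng)
    lat, lon, elev = enu_to_lat_lon_elev(enu)
    return (
        np.column_stack([t_acc, acc]),
        np.column_stack([t_gps, lat, lon, elev]),
    )


def _pocket_rotation(rng: np.random.Generator) -> Rotation:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(0, POCKET_MAX_ROTATION_DEG))
    return Rotation.from_rotvec(axis * angle)


def _small_rotation(rng: np.random.Generator, max_deg: float) -> Rotation:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * math.radians(rng.uniform(0, max_deg)))


def generate_subject(
    subject_id: str,
    profile: CohortProfile,
    schedules: dict[str, tuple[tuple[str, float], ...]],
    rng: np.random.Generator,
) -> SubjectRecord:
    """One subject: both protocol sessions, five placements on one clock."""
    jit = profile.subject_jitter
    locomotions = [a for a in ACTIVITIES if profile.models[a].fundamental_freq_hz]
    freq_off = {a: rng.normal(0, jit.freq_sd_hz) for a in locomotions}
    speed_off = {a: rng.normal(0, jit.speed_sd_mps) for a in locomotions}
    amp_scale = {a: max(0.3, rng.normal(1.0, jit.amp_frac_sd)) for a in locomotions}
    posture_rot = _small_rotation(rng, jit.posture_tilt_deg)

    acc_t: list[np.ndarray] = []
    acc_xyz: dict[str, list[np.ndarray]] = {p: [] for p in POSITIONS}
    gps_t: list[np.ndarray] = []
    gps_enu: list[np.ndarray] = []
    intervals: list[tuple[float, float, str, str]] = []

    cursor = 0.0
    enu = np.zeros(3)
    for protocol in PROTOCOLS:
        inflation = profile.real_life_variance_inflation if protocol == "real_life" else 1.0
        pocket_rot = _pocket_rotation(rng)  # one per session
        for activity, dur in schedules[protocol]:
            model = profile.models[activity]
            gravity = None
            if activity in POSTURES:
                gravity = posture_rot.apply(np.asarray(model.gravity_orientation))
            intervals.append((cursor, cursor + dur, activity, protocol))
            remaining = dur
            while remaining > 1e-9:
                chunk = min(PARAM_REFRESH_S, remaining)
                params = _draw_block_params(
                    model,
                    rng,
                    inflation=inflation,
                    freq_offset=freq_off.get(activity, 0.0),
                    speed_offset=speed_off.get(activity, 0.0),
                    amp_scale=amp_scale.get(activity, 1.0),
                    gravity=gravity,
                )
                gravity_part, dyn, impact = _synth_body_components(params, chunk, FS_ACC_HZ)
                n = gravity_part.shape[0]
                acc_t.append(cursor + np.arange(n) / FS_ACC_HZ)
                for pos in POSITIONS:
                    extra = pocket_rot if pos == "left_pocket" else None
                    sig = _apply_placement(gravity_part, dyn, impact, pos, extra)
                    sig = sig + rng.normal(0, params.noise_sd, sig.shape)
                    acc_xyz[pos].append(sig)
                t_g, enu, fixes = _synth_gps(params, chunk, FS_GPS_HZ, enu, cursor, rng)
                gps_t.append(t_g)
                gps_enu.append(fixes)
                cursor += chunk
                remaining -= chunk
        cursor += SESSION_GAP_S

    t_all = np.concatenate(acc_t)
    acc_streams = {
        pos: AccStream(
            subject_id,
            pos,
            t_all.copy(),
            *(np.concatenate(acc_xyz[pos])[:, i] for i in range(3)),
        )
        for pos in POSITIONS
    }
    enu_all = np.concatenate(gps_enu)
    lat, lon, elev = enu_to_lat_lon_elev(enu_all)
    gps = GpsStream(subject_id, np.concatenate(gps_t), lat, lon, elev)
    labels = LabelTrack(subject_id, intervals)
    return SubjectRecord(subject_id, profile.cohort, acc_streams, gps, labels)


def generate_cohort(
    n_subjects: int,
    profile: CohortProfile,
    schedules: dict[str, tuple[tuple[str, float], ...]] | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Deterministic cohort of ``n_subjects`` records (same seed, same bits)."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    schedules = DEFAULT_SCHEDULES if schedules is None else schedules
    ss = np.random.SeedSequence([seed, sum(map(ord, profile.cohort))])
    children = ss.spawn(n_subjects)
    return [
        generate_subject(
            f"{profile.cohort}_{i:03d}",
            profile,
            schedules,
            np.random.default_rng(children[i]),
        )
        for i in range(n_subjects)
    ]
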