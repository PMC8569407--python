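"""Feature-table assembly and random-forest training/prediction.

Two table scopes mirror the study's model families:

* ``individual:<position>`` — one row per labeled window of that placement
  (85 accelerometer features, optionally + 2 GPS features);
* ``general`` — one row per window start time at which *all five* placements
  produced a window, with the five 85-slot vectors concatenated under
  position-prefixed names (425 columns, optionally + 2 GPS).

GPS features are computed once per window start (the receiver is shared);
in ``acc_gps`` mode, windows with fewer than two fixes are dropped and the
drop is counted, while ``acc`` mode keeps them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import POSITIONS, __version__
from .acc_features import FEATURE_NAMES, acc_feature_vector
from .gps_features import GPS_FEATURE_NAMES, window_gps_features
from .segmentation import SegmentationConfig, segment
from .sensor_io import SubjectRecord

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("subject_id", "cohort", "protocol", "label", "t_start")


@dataclass(frozen=True)
class ModelConfig:
    """Sensor mode, scope and random-forest hyperparameters."""

    sensor_mode: str = "acc"  # acc | acc_gps
    scope: str = "general"  # general | individual:<position>
    n_trees: int = 500
    max_features_rule: str = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sensor_mode not in ("acc", "acc_gps"):
            raise ValueError(f"unknown sensor_mode {self.sensor_mode!r}")
        if self.scope != "general":
            prefix, _, pos = self.scope.partition(":")
            if prefix != "individual" or pos not in POSITIONS:
                raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def position(self) -> str | None:
        return None if self.scope == "general" else self.scope.split(":", 1)[1]


@dataclass
class FeatureTable:
    """Windows x features with metadata columns kept out of the classifier."""

    frame: pd.DataFrame
    feature_columns: tuple[str, ...]
    n_gps_dropped: int = 0

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[list(self.feature_columns)]

    @property
    def y(self) -> pd.Series:
        return self.frame["label"]


@dataclass
class TrainedModel:
    classifier: RandomForestClassifier
    config: ModelConfig
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    package_version: str = __version__


def extract_position_features(
    record: SubjectRecord,
    position: str,
    seg_cfg: SegmentationConfig,
    cache: dict | None = None,
) -> pd.DataFrame:
    """Labeled-window features of one placement (may be empty).

    Columns: t_start, label, protocol, the 85 accelerometer features, the two
    GPS features and a gps_valid flag.  Feature extraction dominates pipeline
    cost, so callers evaluating several model configurations over the same
    records can pass a shared ``cache`` dict keyed by (subject_id, position).
    """
    key = (record.subject_id, position)
    if cache is not None and key in cache:
        return cache[key]
    rows = []
    for w in segment(record, position, seg_cfg):
        if w.label is None:
            continue
        feats = acc_feature_vector(w.acc_block, seg_cfg.fs_nominal_hz)
        pair = window_gps_features(w.gps_fixes)
        feats["t_start"] = w.t_start
        feats["label"] = w.label
        feats["protocol"] = w.protocol
        feats["gps_avg_speed"] = pair.avg_speed
        feats["gps_elev_diff"] = pair.elev_diff
        feats["gps_valid"] = pair.valid
        rows.append(feats)
    df = pd.DataFrame(rows)
    if cache is not None:
        cache[key] = df
    return df


def _subject_window_features(
    record: SubjectRecord,
    positions: list[str],
    seg_cfg: SegmentationConfig,
    cache: dict | None,
) -> pd.DataFrame | None:
    """Per-position window features aligned on window start time."""
    per_pos: list[pd.DataFrame] = []
    prefix = len(positions) > 1
    for pos in positions:
        df = extract_position_features(record, pos, seg_cfg, cache)
        if not len(df):
            return None
        df = df.set_index("t_start")
        if prefix:
            df = df.rename(columns={n: f"{pos}_{n}" for n in FEATURE_NAMES})
        per_pos.append(df)
    if len(per_pos) == 1:
        merged = per_pos[0]
    else:
        # label/protocol/GPS come from the first position; alignment is exact
        shared = ["label", "protocol", "gps_avg_speed", "gps_elev_diff", "gps_valid"]
        base = per_pos[0]
        others = [d.drop(columns=shared) for d in per_pos[1:]]
        merged = base.join(others, how="inner")
    merged = merged.reset_index()
    merged["subject_id"] = record.subject_id
    merged["cohort"] = record.cohort
    return merged


def build_feature_table(
    records: list[SubjectRecord],
    config: ModelConfig,
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    cache: dict | None = None,
) -> FeatureTable:
    """Assemble the labeled-window feature table for a model configuration.

    General scope requires all five placements per subject; subjects missing
    one are excluded with a logged warning.  In ``acc_gps`` mode windows
    without a valid GPS pair are dropped (counted in ``n_gps_dropped``).
    """
    if config.scope == "general":
        positions = list(POSITIONS)
        feature_cols = tuple(f"{p}_{n}" for p in POSITIONS for n in FEATURE_NAMES)
    else:
        positions = [config.position]
        feature_cols = FEATURE_NAMES
    if config.sensor_mode == "acc_gps":
        feature_cols = tuple(feature_cols) + GPS_FEATURE_NAMES

    frames = []
    for record in records:
        missing = [p for p in positions if p not in record.acc]
        if missing:
            logger.warning(
                "subject %s excluded: missing positions %s", record.subject_id, missing
            )
            continue
        df = _subject_window_features(record, positions, seg_cfg, cache)
        if df is not None:
            frames.append(df)
    if not frames:
        frame = pd.DataFrame(columns=list(METADATA_COLUMNS) + list(feature_cols))
        return FeatureTable(frame, tuple(feature_cols), 0)
    frame = pd.concat(frames, ignore_index=True)

    n_dropped = 0
    if config.sensor_mode == "acc_gps":
        keep = frame["gps_valid"].astype(bool)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropped %d windows without valid GPS", n_dropped)
        frame = frame[keep].reset_index(drop=True)
    frame = frame.drop(columns=["gps_valid"])
    if config.sensor_mode == "acc":
        frame = frame.drop(columns=list(GPS_FEATURE_NAMES))
    frame = frame[list(METADATA_COLUMNS) + list(feature_cols)]
    if frame[list(feature_cols)].isna().any().any():
        raise ValueError("feature table contains missing values")
    return FeatureTable(frame, tuple(feature_cols), n_dropped)


def train(table: FeatureTable, config: ModelConfig) -> TrainedModel:
    """Fit a random forest on the table; deterministic for a given seed."""
    y = table.y
    classes = tuple(sorted(y.unique()))
    if len(classes) < 2:
        raise ValueError("training table must contain at least 2 classes")
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features_rule,
        random_state=config.seed,
        n_jobs=1,
    )
    clf.fit(table.X.to_numpy(), y.to_numpy())
    return TrainedModel(clf, config, tuple(table.feature_columns), classes)


def predict(model: TrainedModel, table: FeatureTable | pd.DataFrame) -> np.ndarray:
    """Predicted labels, aligning columns by name; schema mismatch is fatal."""
    frame = table.frame if isinstance(table, FeatureTable) else table
    have = set(c for c in frame.columns if c not in METADATA_COLUMNS)
    want = set(model.feature_names)
    missing, extra = want - have, have - want
    if missing or extra:
        raise ValueError(
            f"feature schema mismatch: missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
        )
    if not len(frame):
        return np.array([], dtype=object)
    X = frame[list(model.feature_names)].to_numpy()
    return model.classifier.predict(X)


def save_model(model: TrainedModel, path) -> None:
    """Persist config, feature order, class list and fitted state."""
    joblib.dump(
        {
            "package_version": model.package_version,
            "config": model.config,
            "feature_names": model.feature_names,
            "classes": model.classes,
            "classifier": model.classifier,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    """Load a persisted model; refuses across incompatible package versions."""
    payload = joblib.load(path)
    saved = str(payload["package_version"])
    if saved.rsplit(".", 1)[0] != __version__.rsplit(".", 1)[0]:
        raise ValueError(
            f"model saved by package {saved}, incompatible with {__version__}"
        )
    return TrainedModel(
        payload["classifier"],
        payload["config"],
        tuple(payload["feature_names"]),
        tuple(payload["classes"]),
        saved,
    )
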