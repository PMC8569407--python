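"""Leave-one-subject-out evaluation designs and classification metrics.

The evaluation grid crosses protocol *scenarios* with age-cohort *designs*:

scenarios (training protocol composition x test protocol)
    S1A  train semi-structured,  test semi-structured
    S1B  train semi-structured,  test real-life
    S2A  train combined,         test combined
    S2B  train combined,         test real-life
    S3A  train real-life,        test real-life

age designs (training cohorts -> test cohort)
    within_old           old -> old
    within_young         young -> young
    y_trained_btw        young -> old
    yando_trained_btw    young + old -> old

Folds always run over the *test* cohort's subjects; a held-out subject is
excluded from training entirely (both cohorts, all protocols), while
training-only cohorts (e.g. the young cohort in ``y_trained_btw``) are never
folded.  Metrics are micro-pooled over folds, and per-held-out-subject
accuracies are kept for distribution summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ACTIVITIES
from .modeling import FeatureTable, ModelConfig, build_feature_table, predict, train
from .segmentation import SegmentationConfig
from .sensor_io import SubjectRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    train_protocols: frozenset[str]
    test_protocols: frozenset[str]


@dataclass(frozen=True)
class AgeModelSpec:
    id: str
    train_cohorts: frozenset[str]
    test_cohort: str


SCENARIOS: dict[str, ScenarioSpec] = {
    s.id: s
    for s in (
        ScenarioSpec("S1A", frozenset({"semi_structured"}), frozenset({"semi_structured"})),
        ScenarioSpec("S1B", frozenset({"semi_structured"}), frozenset({"real_life"})),
        ScenarioSpec("S2A", frozenset({"semi_structured", "real_life"}),
                     frozenset({"semi_structured", "real_life"})),
        ScenarioSpec("S2B", frozenset({"semi_structured", "real_life"}), frozenset({"real_life"})),
        ScenarioSpec("S3A", frozenset({"real_life"}), frozenset({"real_life"})),
    )
}

AGE_DESIGNS: dict[str, AgeModelSpec] = {
    a.id: a
    for a in (
        AgeModelSpec("within_old", frozenset({"old"}), "old"),
        AgeModelSpec("within_young", frozenset({"young"}), "young"),
        AgeModelSpec("y_trained_btw", frozenset({"young"}), "old"),
        AgeModelSpec("yando_trained_btw", frozenset({"young", "old"}), "old"),
    )
}


@dataclass
class ConfusionMatrix:
    """K x K counts over the activity classes; rows truth, columns prediction."""

    classes: tuple[str, ...]
    counts: np.ndarray

    @classmethod
    def empty(cls, classes: tuple[str, ...] = ACTIVITIES) -> "ConfusionMatrix":
        return cls(tuple(classes), np.zeros((len(classes), len(classes)), dtype=int))

    @classmethod
    def from_labels(cls, truth, pred, classes: tuple[str, ...] = ACTIVITIES) -> "ConfusionMatrix":
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(truth, pred):
            counts[idx[t], idx[p]] += 1
        return cls(tuple(classes), counts)

    def add(self, other: "ConfusionMatrix") -> None:
        if self.classes != other.classes:
            raise ValueError("class vocabularies differ")
        self.counts += other.counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


def overall_accuracy(confusion: ConfusionMatrix) -> float:
    """100 * trace / total of the matrix."""
    if confusion.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(confusion.counts)) / confusion.total


def precision_recall_f1(confusion: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision/recall/F1 in percent; zero denominators map to 0."""
    counts = confusion.counts
    out = {}
    for i, cls in enumerate(confusion.classes):
        tp = float(counts[i, i])
        col = float(counts[:, i].sum())
        row = float(counts[i, :].sum())
        precision = 100.0 * tp / col if col > 0 else 0.0
        recall = 100.0 * tp / row if row > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        out[cls] = {"precision": precision, "recall": recall, "f1": f1}
    return pd.DataFrame(out).T[["precision", "recall", "f1"]]


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (inputs and output in percent)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def confusion_pair_rate(confusion: ConfusionMatrix, class_a: str, class_b: str) -> float:
    """Percent of true a/b windows predicted as the other class of the pair."""
    if class_a == class_b:
        raise ValueError("classes must be distinct")
    ia = confusion.classes.index(class_a)
    ib = confusion.classes.index(class_b)
    denom = float(confusion.counts[ia, :].sum() + confusion.counts[ib, :].sum())
    if denom == 0:
        return 0.0
    cross = float(confusion.counts[ia, ib] + confusion.counts[ib, ia])
    return 100.0 * cross / denom


def l1so_folds(subject_ids: list[str]) -> list[tuple[list[str], str]]:
    """Leave-one-subject-out folds: one (train_ids, test_id) pair per subject."""
    ids = list(subject_ids)
    if len(ids) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [([s for s in ids if s != held], held) for held in ids]


def plan_folds(
    records: list[SubjectRecord],
    scenario: ScenarioSpec,
    age_spec: AgeModelSpec,
) -> list[tuple[list[str], str]]:
    """Structural fold plan: folds over the test cohort's subjects only."""
    test_ids = sorted(r.subject_id for r in records if r.cohort == age_spec.test_cohort)
    return l1so_folds(test_ids)


def fold_partitions(
    frame: pd.DataFrame,
    scenario: ScenarioSpec | str,
    age_spec: AgeModelSpec | str,
    folds: list[tuple[list[str], str]],
):
    """Yield (held_out, train_mask, test_mask) over a feature-table frame.

    This is the single partitioning rule the evaluation uses: training rows
    come from the design's training cohorts and the scenario's training
    protocols with the held-out subject excluded entirely; test rows are the
    held-out subject's windows in the test cohort and test protocols.
    """
    scenario = SCENARIOS[scenario] if isinstance(scenario, str) else scenario
    age_spec = AGE_DESIGNS[age_spec] if isinstance(age_spec, str) else age_spec
    train_cohort_mask = frame["cohort"].isin(age_spec.train_cohorts)
    train_proto_mask = frame["protocol"].isin(scenario.train_protocols)
    test_proto_mask = frame["protocol"].isin(scenario.test_protocols)
    for _train_ids, held_out in folds:
        train_mask = train_cohort_mask & train_proto_mask & (frame["subject_id"] != held_out)
        test_mask = (
            (frame["subject_id"] == held_out)
            & (frame["cohort"] == age_spec.test_cohort)
            & test_proto_mask
        )
        yield held_out, train_mask, test_mask


@dataclass
class EvaluationReport:
    scenario_id: str
    age_design_id: str
    model_config: ModelConfig
    classes: tuple[str, ...]
    pooled: ConfusionMatrix
    per_fold: dict[str, ConfusionMatrix]
    subject_accuracy: dict[str, float]
    n_gps_dropped: int
    skipped_folds: list[str] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return overall_accuracy(self.pooled)

    def per_class_metrics(self) -> pd.DataFrame:
        return precision_recall_f1(self.pooled)

    def to_json_dict(self) -> dict:
        return {
            "scenario": self.scenario_id,
            "age_design": self.age_design_id,
            "sensor_mode": self.model_config.sensor_mode,
            "scope": self.model_config.scope,
            "classes": list(self.classes),
            "overall_accuracy": self.accuracy,
            "per_class": {
                cls: dict(row)
                for cls, row in self.per_class_metrics().round(4).iterrows()
            },
            "pooled_confusion": self.pooled.counts.tolist(),
            "subject_accuracy": self.subject_accuracy,
            "n_gps_dropped": self.n_gps_dropped,
            "skipped_folds": self.skipped_folds,
        }

    def save(self, directory: str | Path, stem: str) -> None:
        """JSON report, human-readable table, and confusion matrix CSV."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / f"{stem}.json", "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        self.pooled.to_frame().to_csv(d / f"{stem}_confusion.csv")
        with open(d / f"{stem}.txt", "w", encoding="utf-8") as fh:
            fh.write(f"{self.scenario_id} x {self.age_design_id} "
                     f"({self.model_config.sensor_mode}, {self.model_config.scope})\n")
            fh.write(f"overall accuracy: {self.accuracy:.2f}%\n\n")
            fh.write(self.per_class_metrics().round(2).to_string())
            fh.write("\n")


def run_design(
    records: list[SubjectRecord],
    scenario: ScenarioSpec | str,
    age_spec: AgeModelSpec | str,
    model_cfg: ModelConfig = ModelConfig(),
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    table: FeatureTable | None = None,
) -> EvaluationReport:
    """Run one (scenario x age design) cell with leave-one-subject-out folds.

    A pre-built feature table for the same records/config can be passed to
    avoid recomputing features across cells.  Folds with an empty test
    partition are skipped with a warning; if every fold is empty the cell is
    infeasible and raises.
    """
    scenario = SCENARIOS[scenario] if isinstance(scenario, str) else scenario
    age_spec = AGE_DESIGNS[age_spec] if isinstance(age_spec, str) else age_spec
    if table is None:
        table = build_feature_table(records, model_cfg, seg_cfg)
    frame = table.frame

    folds = plan_folds(records, scenario, age_spec)
    pooled = ConfusionMatrix.empty(ACTIVITIES)
    per_fold: dict[str, ConfusionMatrix] = {}
    subject_accuracy: dict[str, float] = {}
    skipped: list[str] = []

    # When the test cohort never contributes training rows (pure between-age
    # transfer), the training set is identical in every fold: fit once.
    static_train = age_spec.test_cohort not in age_spec.train_cohorts
    static_model = None

    for held_out, train_mask, test_mask in fold_partitions(frame, scenario, age_spec, folds):
        if not test_mask.any():
            logger.warning("fold %s skipped: empty test partition", held_out)
            skipped.append(held_out)
            continue
        if static_train:
            if static_model is None:
                static_model = train(FeatureTable(frame[train_mask], table.feature_columns), model_cfg)
            model = static_model
        else:
            train_table = FeatureTable(frame[train_mask], table.feature_columns)
            model = train(train_table, model_cfg)
        test_frame = frame[test_mask]
        pred = predict(model, test_frame)
        cm = ConfusionMatrix.from_labels(test_frame["label"], pred, ACTIVITIES)
        per_fold[held_out] = cm
        subject_accuracy[held_out] = overall_accuracy(cm)
        pooled.add(cm)
    if not per_fold:
        raise ValueError(
            f"all folds empty for {scenario.id} x {age_spec.id}: infeasible cell"
        )
    return EvaluationReport(
        scenario_id=scenario.id,
        age_design_id=age_spec.id,
        model_config=model_cfg,
        classes=ACTIVITIES,
        pooled=pooled,
        per_fold=per_fold,
        subject_accuracy=subject_accuracy,
        n_gps_dropped=table.n_gps_dropped,
        skipped_folds=skipped,
    )
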