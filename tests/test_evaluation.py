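"""Fold construction, metric arithmetic, and the scenario/age design grid."""

import numpy as np
import pytest

from patd import ACTIVITIES
from patd.evaluation import (
    AGE_DESIGNS,
    SCENARIOS,
    ConfusionMatrix,
    confusion_pair_rate,
    f1_from_pr,
    l1so_folds,
    overall_accuracy,
    plan_folds,
    precision_recall_f1,
    run_design,
)
from patd.modeling import ModelConfig, build_feature_table


class TestL1soFolds:
    def test_five_subjects_five_folds(self):
        ids = [f"s{i}" for i in range(5)]
        folds = l1so_folds(ids)
        assert len(folds) == 5
        assert all(len(train) == 4 for train, _ in folds)

    def test_test_singletons_cover_all_ids(self):
        ids = [f"s{i}" for i in range(7)]
        assert {held for _, held in l1so_folds(ids)} == set(ids)

    def test_no_fold_trains_on_its_test_subject(self):
        for train, held in l1so_folds([f"s{i}" for i in range(6)]):
            assert held not in train

    def test_single_subject_is_hard_error(self):
        with pytest.raises(ValueError):
            l1so_folds(["only"])


class TestRegistries:
    def test_scenario_protocol_compositions(self):
        assert SCENARIOS["S1A"].train_protocols == {"semi_structured"}
        assert SCENARIOS["S1B"].test_protocols == {"real_life"}
        assert SCENARIOS["S2A"].train_protocols == {"semi_structured", "real_life"}
        assert SCENARIOS["S2B"].test_protocols == {"real_life"}
        assert SCENARIOS["S3A"].train_protocols == {"real_life"}

    def test_age_design_cohort_flow(self):
        assert AGE_DESIGNS["within_old"].train_cohorts == {"old"}
        assert AGE_DESIGNS["within_old"].test_cohort == "old"
        assert AGE_DESIGNS["y_trained_btw"].train_cohorts == {"young"}
        assert AGE_DESIGNS["y_trained_btw"].test_cohort == "old"
        assert AGE_DESIGNS["yando_trained_btw"].train_cohorts == {"young", "old"}


def cm(counts):
    return ConfusionMatrix(ACTIVITIES, np.array(counts, dtype=int))


class TestMetrics:
    # (precision, recall, printed F1) rows from the worked per-participant
    # tables whose printed triples are arithmetically self-consistent
    SELF_CONSISTENT_ROWS = [
        (64.73, 100.0, 78.59),   # non-level walking, ACC, older participant
        (90.70, 99.15, 94.74),   # running, ACC, older participant
        (94.40, 100.0, 97.12),   # running, ACC+GPS, older participant
        (97.34, 72.91, 83.37),   # walking, ACC+GPS, older participant
        (88.01, 59.24, 70.81),   # non-level walking, ACC, younger participant
        (91.24, 94.63, 92.90),   # walking, ACC+GPS, younger participant
    ]
    # rows whose printed F1 was evidently computed from unrounded P/R: the
    # harmonic mean of the printed pair lands within input-rounding slack
    ROUNDING_LIMITED_ROWS = [
        (100.0, 20.72, 34.32),
        (84.63, 98.53, 91.06),
        (51.76, 84.43, 64.17),
        (100.0, 99.13, 99.56),
        (99.12, 100.0, 99.56),
        (96.92, 95.45, 96.18),
        (100.0, 98.25, 99.12),
    ]

    @pytest.mark.parametrize("p,r,f1", SELF_CONSISTENT_ROWS)
    def test_f1_recovers_published_values(self, p, r, f1):
        assert f1_from_pr(p, r) == pytest.approx(f1, abs=0.005)

    @pytest.mark.parametrize("p,r,f1", ROUNDING_LIMITED_ROWS)
    def test_f1_within_input_rounding_of_published_values(self, p, r, f1):
        # printed P/R carry +-0.005 rounding each, propagating to ~+-0.015 on F1
        assert f1_from_pr(p, r) == pytest.approx(f1, abs=0.015)

    def test_diagonal_matrix_gives_perfect_metrics(self):
        mat = cm(np.diag([5, 4, 3, 2, 1, 6]))
        metrics = precision_recall_f1(mat)
        assert np.allclose(metrics.to_numpy(), 100.0)
        assert overall_accuracy(mat) == 100.0
        assert confusion_pair_rate(mat, "running", "walking") == 0.0

    def test_uniform_matrix_accuracy_is_one_sixth(self):
        mat = cm(np.ones((6, 6)))
        assert overall_accuracy(mat) == pytest.approx(100.0 / 6)

    def test_zero_denominator_conventions(self):
        counts = np.zeros((6, 6), int)
        counts[0, 1] = 4  # lying always predicted sitting
        mat = cm(counts)
        metrics = precision_recall_f1(mat)
        assert metrics.loc["lying", "recall"] == 0.0
        assert metrics.loc["lying", "precision"] == 0.0  # empty column -> 0
        assert metrics.loc["lying", "f1"] == 0.0

    def test_random_matrix_matches_brute_force(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 20, (6, 6))
        mat = cm(counts)
        assert overall_accuracy(mat) == pytest.approx(
            100.0 * counts.trace() / counts.sum()
        )
        metrics = precision_recall_f1(mat)
        for i, cls in enumerate(ACTIVITIES):
            p = 100 * counts[i, i] / counts[:, i].sum()
            r = 100 * counts[i, i] / counts[i, :].sum()
            assert metrics.loc[cls, "precision"] == pytest.approx(p)
            assert metrics.loc[cls, "recall"] == pytest.approx(r)
            assert metrics.loc[cls, "f1"] == pytest.approx(f1_from_pr(p, r))

    def test_pair_rate_closed_forms(self):
        counts = np.zeros((6, 6), int)
        iw, ir = ACTIVITIES.index("walking"), ACTIVITIES.index("running")
        counts[ir, iw] = 10  # all running predicted walking
        counts[iw, iw] = 30
        mat = cm(counts)
        assert confusion_pair_rate(mat, "running", "walking") == pytest.approx(100 * 10 / 40)
        with pytest.raises(ValueError):
            confusion_pair_rate(mat, "walking", "walking")

    def test_empty_matrix_is_hard_error(self):
        with pytest.raises(ValueError):
            overall_accuracy(cm(np.zeros((6, 6), int)))


@pytest.fixture(scope="module")
def six_subjects(tiny_cohorts):
    young, old = tiny_cohorts
    return list(young) + list(old)


@pytest.fixture(scope="module")
def small_table(six_subjects):
    return build_feature_table(six_subjects, ModelConfig("acc", "individual:right_knee", n_trees=15))


class TestRunDesign:
    CFG = ModelConfig("acc", "individual:right_knee", n_trees=15, seed=0)

    def test_within_young_s1a_window_accounting(self, six_subjects, small_table):
        """Pooled test totals equal the young cohort's labeled semi-structured
        windows, and per-fold matrices sum to the pooled matrix."""
        report = run_design(six_subjects, "S1A", "within_young", self.CFG, table=small_table)
        frame = small_table.frame
        expected = len(
            frame[(frame.cohort == "young") & (frame.protocol == "semi_structured")]
        )
        assert report.pooled.total == expected
        assert report.pooled.total == sum(m.total for m in report.per_fold.values())

    def test_variant_b_tests_only_real_life(self, six_subjects, small_table):
        report = run_design(six_subjects, "S1B", "within_young", self.CFG, table=small_table)
        frame = small_table.frame
        expected = len(frame[(frame.cohort == "young") & (frame.protocol == "real_life")])
        assert report.pooled.total == expected

    def test_between_age_designs_fold_only_over_old(self, six_subjects):
        for design in ("y_trained_btw", "yando_trained_btw"):
            folds = plan_folds(six_subjects, SCENARIOS["S1A"], AGE_DESIGNS[design])
            held = {h for _, h in folds}
            old_ids = {r.subject_id for r in six_subjects if r.cohort == "old"}
            assert held == old_ids

    def test_accuracy_consistent_with_pooled_matrix(self, six_subjects, small_table):
        report = run_design(six_subjects, "S2A", "within_old", self.CFG, table=small_table)
        assert report.accuracy == pytest.approx(overall_accuracy(report.pooled))
        metrics = report.per_class_metrics()
        assert set(metrics.index) == set(ACTIVITIES)

    def test_report_serialization(self, six_subjects, small_table, tmp_path):
        report = run_design(six_subjects, "S1A", "within_old", self.CFG, table=small_table)
        report.save(tmp_path, "cell")
        assert (tmp_path / "cell.json").exists()
        assert (tmp_path / "cell_confusion.csv").exists()
        import json

        payload = json.loads((tmp_path / "cell.json").read_text())
        assert payload["overall_accuracy"] == pytest.approx(report.accuracy)
        assert np.array(payload["pooled_confusion"]).sum() == report.pooled.total
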