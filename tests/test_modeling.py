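"""Feature-table assembly, RF training determinism, and model persistence."""

import numpy as np
import pandas as pd
import pytest

from patd import POSITIONS
from patd.acc_features import FEATURE_NAMES
from patd.modeling import (
    FeatureTable,
    ModelConfig,
    build_feature_table,
    load_model,
    predict,
    save_model,
    train,
)
from patd.segmentation import SegmentationConfig


@pytest.fixture(scope="module")
def young3(tiny_cohorts):
    return tiny_cohorts[0]


@pytest.fixture(scope="module")
def cache():
    return {}


class TestModelConfig:
    def test_rejects_unknown_scope_and_mode(self):
        with pytest.raises(ValueError):
            ModelConfig(scope="individual:ankle")
        with pytest.raises(ValueError):
            ModelConfig(sensor_mode="audio")

    def test_position_accessor(self):
        assert ModelConfig(scope="individual:right_knee").position == "right_knee"
        assert ModelConfig(scope="general").position is None


class TestBuildFeatureTable:
    def test_individual_scope_has_85_feature_columns(self, young3, cache):
        cfg = ModelConfig("acc", "individual:chest", n_trees=10)
        table = build_feature_table(young3, cfg, cache=cache)
        assert table.feature_columns == FEATURE_NAMES
        assert len(table.feature_columns) == 85
        assert len(table.frame) > 0
        assert not table.frame[list(table.feature_columns)].isna().any().any()

    def test_general_scope_concatenates_425_columns(self, young3, cache):
        cfg = ModelConfig("acc", "general", n_trees=10)
        table = build_feature_table(young3, cfg, cache=cache)
        assert len(table.feature_columns) == 425
        assert all(
            any(c.startswith(f"{p}_") for c in table.feature_columns) for p in POSITIONS
        )

    def test_acc_gps_appends_two_features(self, young3, cache):
        cfg = ModelConfig("acc_gps", "general", n_trees=10)
        table = build_feature_table(young3, cfg, cache=cache)
        assert len(table.feature_columns) == 427
        assert table.feature_columns[-2:] == ("gps_avg_speed", "gps_elev_diff")

    def test_general_rows_at_most_min_of_individual(self, young3, cache):
        general = build_feature_table(young3, ModelConfig("acc", "general", n_trees=10), cache=cache)
        per_pos = [
            len(build_feature_table(young3, ModelConfig("acc", f"individual:{p}", n_trees=10), cache=cache).frame)
            for p in POSITIONS
        ]
        assert len(general.frame) <= min(per_pos)

    def test_subject_missing_position_excluded_from_general(self, young3, cache):
        import copy

        crippled = copy.copy(young3[0])
        crippled.acc = {k: v for k, v in young3[0].acc.items() if k != "chest"}
        table = build_feature_table([crippled] + list(young3[1:]),
                                    ModelConfig("acc", "general", n_trees=10))
        assert crippled.subject_id not in set(table.frame["subject_id"])

    def test_gpsless_subject_dropped_rows_counted(self, young3, cache):
        import copy

        no_gps = copy.copy(young3[0])
        no_gps.gps = None
        table = build_feature_table([no_gps], ModelConfig("acc_gps", "individual:chest", n_trees=10))
        assert len(table.frame) == 0
        assert table.n_gps_dropped > 0
        acc_table = build_feature_table([no_gps], ModelConfig("acc", "individual:chest", n_trees=10))
        assert len(acc_table.frame) > 0  # ACC-only keeps the windows


@pytest.fixture(scope="module")
def table(young3):
    return build_feature_table(young3, ModelConfig("acc", "individual:right_knee", n_trees=30))


class TestTrainPredict:
    def test_training_rows_repredicted_from_vocabulary(self, table, young3):
        cfg = ModelConfig("acc", "individual:right_knee", n_trees=30, seed=1)
        model = train(table, cfg)
        pred = predict(model, table)
        assert set(pred) <= set(model.classes)
        assert len(pred) == len(table.frame)

    def test_seed_determinism(self, table):
        cfg = ModelConfig("acc", "individual:right_knee", n_trees=30, seed=5)
        p1 = predict(train(table, cfg), table)
        p2 = predict(train(table, cfg), table)
        assert np.array_equal(p1, p2)

    def test_column_permutation_is_harmless(self, table):
        cfg = ModelConfig("acc", "individual:right_knee", n_trees=30, seed=5)
        model = train(table, cfg)
        shuffled = table.frame[list(table.frame.columns[::-1])]
        assert np.array_equal(predict(model, table), predict(model, shuffled))

    def test_schema_mismatch_is_fatal_and_named(self, table):
        cfg = ModelConfig("acc", "individual:right_knee", n_trees=30)
        model = train(table, cfg)
        broken = table.frame.rename(columns={"mean_x": "mean_q"})
        with pytest.raises(ValueError, match="mean_"):
            predict(model, broken)

    def test_empty_table_predicts_empty(self, table):
        cfg = ModelConfig("acc", "individual:right_knee", n_trees=30)
        model = train(table, cfg)
        assert len(predict(model, table.frame.iloc[:0])) == 0

    def test_single_class_table_rejected(self, table):
        cfg = ModelConfig("acc", "individual:right_knee", n_trees=30)
        walking_only = table.frame[table.frame["label"] == "walking"]
        with pytest.raises(ValueError, match="class"):
            train(FeatureTable(walking_only, table.feature_columns), cfg)

    def test_separable_toy_table_fits_perfectly(self):
        rng = np.random.default_rng(0)
        n = 60
        frame = pd.DataFrame(
            {name: rng.normal(0, 0.01, n) for name in FEATURE_NAMES}
        )
        frame["mean_x"] = np.r_[np.zeros(30), np.ones(30)]
        frame["label"] = ["sitting"] * 30 + ["walking"] * 30
        frame["subject_id"] = "s"
        frame["cohort"] = "young"
        frame["protocol"] = "semi_structured"
        frame["t_start"] = np.arange(n, dtype=float)
        table = FeatureTable(frame, FEATURE_NAMES)
        model = train(table, ModelConfig("acc", "individual:chest", n_trees=20, seed=0))
        assert np.mean(predict(model, table) == frame["label"]) == 1.0


class TestPersistence:
    def test_round_trip(self, tmp_path, young3):
        table = build_feature_table(young3, ModelConfig("acc", "individual:chest", n_trees=10))
        cfg = ModelConfig("acc", "individual:chest", n_trees=10, seed=2)
        model = train(table, cfg)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.feature_names == model.feature_names
        assert loaded.classes == model.classes
        assert np.array_equal(predict(loaded, table), predict(model, table))

    def test_version_gate(self, tmp_path, young3):
        table = build_feature_table(young3, ModelConfig("acc", "individual:chest", n_trees=10))
        model = train(table, ModelConfig("acc", "individual:chest", n_trees=10))
        model.package_version = "99.0.0"
        path = tmp_path / "model.joblib"
        save_model(model, path)
        with pytest.raises(ValueError, match="incompatible"):
            load_model(path)
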