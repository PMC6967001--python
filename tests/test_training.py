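import warnings

import numpy as np
import pandas as pd
import pytest

import abdev
from abdev.errors import SuiteFormatError, TrainingError
from abdev.io import Dataset
from abdev.preprocessing import invert_orq
from abdev.training import (CvResult, CvSettings, cross_validate,
                            default_configs, load_suite, make_folds,
                            resolve_threshold, save_suite, select_model,
                            train_platform)


class TestMakeFolds:
    def test_partition_property(self):
        folds = make_folds(20, folds=10, repeats=3, seed=1)
        assert folds.shape == (3, 20)
        for r in range(3):
            sizes = np.bincount(folds[r], minlength=10)
            assert (sizes == 2).all()

    def test_reference_panel_sizes(self):
        folds = make_folds(137, folds=10, repeats=2, seed=0)
        sizes = np.bincount(folds[0], minlength=10)
        assert set(sizes) == {13, 14}
        assert sizes.sum() == 137

    def test_deterministic_and_repeat_distinct(self):
        a = make_folds(30, folds=5, repeats=4, seed=9)
        b = make_folds(30, folds=5, repeats=4, seed=9)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a[0], a[1])

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="fewer folds"):
            make_folds(5, folds=10, repeats=1, seed=0)


class TestCrossValidate:
    def test_noiseless_linear_data_interpolated(self, rng):
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        y = (2 * X["a"] - X["c"]).to_numpy()
        folds = make_folds(n, folds=5, repeats=1, seed=0)
        grids = {"elastic_net": {"l1_ratio": [0.0], "n_alphas": 1,
                                 "alpha_min": 1e-12, "alpha_max": 1e-12}}
        res = cross_validate(("elastic_net", "vif_all", "identity"),
                             X, y, folds, grids=grids)
        assert res.mae < 1e-6
        assert res.r2 > 1 - 1e-9

    def test_out_of_fold_count_conservation(self, rng):
        n, repeats = 40, 3
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + 0.1 * rng.normal(size=n)
        folds = make_folds(n, folds=5, repeats=repeats, seed=2)
        res = cross_validate(("elastic_net", "vif_all", "identity"),
                             X, y, folds)
        assert res.folds * len(res.fold_mae) // res.folds == repeats * 5
        # every row lands in exactly one validation fold per repeat
        for r in range(repeats):
            assert np.bincount(folds[r]).sum() == n


class TestSelectModel:
    def _cv(self, mae):
        return CvResult(mae=mae, r2=0.5, fold_mae=[mae], repeats=1,
                        folds=5, seed=0)

    def test_single_candidate_wins(self):
        winner = select_model([(("svm_rbf", "vif_all", "identity"),
                                self._cv(1.0))])
        assert winner[0][0] == "svm_rbf"

    def test_lower_mae_wins(self):
        winner = select_model([
            (("random_forest", "vif_all", "identity"), self._cv(1.0)),
            (("svm_rbf", "vif_all", "identity"), self._cv(2.0)),
        ])
        assert winner[0][0] == "random_forest"

    def test_tie_breaks_toward_simpler_model(self):
        winner = select_model([
            (("random_forest", "vif_all", "identity"), self._cv(1.0)),
            (("elastic_net", "vif_all", "identity"), self._cv(1.0)),
        ])
        assert winner[0][0] == "elastic_net"
        winner = select_model([
            (("elastic_net", "vif_all", "identity"), self._cv(1.0)),
            (("elastic_net", "vif_selected", "identity"), self._cv(1.0)),
        ])
        assert winner[0][1] == "vif_selected"

    def test_no_candidates_is_error(self):
        with pytest.raises(TrainingError):
            select_model([])


class TestCensoring:
    def test_censored_rows_excluded_from_training(self):
        records = abdev.generate_fv(seed=4, n=30)
        meas = pd.DataFrame(
            {"HIC": [25.0] * 6 + list(np.linspace(7, 12, 24))},
            index=[r.id for r in records])
        ds = Dataset(records=records, measurements=meas)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_platform(ds, "HIC",
                                   cv=CvSettings(folds=5, repeats=1, seed=1))
        assert len(model.reference_ids) == 24
        assert (model.reference_raw < 25).all()

    def test_too_few_rows_refused_with_count(self):
        records = abdev.generate_fv(seed=4, n=15)
        meas = pd.DataFrame({"HIC": np.linspace(7, 12, 15)},
                            index=[r.id for r in records])
        ds = Dataset(records=records, measurements=meas)
        with pytest.raises(TrainingError, match="HIC.*15"):
            train_platform(ds, "HIC")


class TestThresholdResolution:
    def test_worst_10pct_higher_better(self):
        cfg = abdev.PlatformConfig(platform="HEK", threshold="worst_10pct",
                                   direction="higher_better")
        values = np.arange(1.0, 101.0)   # 100 distinct titers
        thr = resolve_threshold(cfg, values)
        assert thr == 10.0
        assert int((values <= thr).sum()) == 10

    def test_worst_10pct_lower_better(self):
        cfg = abdev.PlatformConfig(platform="PSR", threshold="worst_10pct",
                                   direction="lower_better")
        values = np.arange(1.0, 101.0)
        thr = resolve_threshold(cfg, values)
        assert int((values >= thr).sum()) == 10

    def test_numeric_threshold_passes_through(self):
        cfg = abdev.PlatformConfig(platform="HIC", threshold=11.7)
        assert resolve_threshold(cfg, np.arange(10.0)) == 11.7


class TestTrainedSuite:
    def test_table_layout_defaults(self):
        """The packaged defaults pin algorithm/variables/transform per

        platform rather than re-selecting them on every run."""
        configs = default_configs()
        assert set(configs) == set(abdev.config.PLATFORMS)
        assert configs["HIC"].algorithm == "elastic_net"
        assert configs["HIC"].variables == "vif_selected"
        assert configs["HIC"].censor_value == 25
        assert configs["ELISA"].algorithm == "random_forest"
        assert configs["CSI"].transform == "ordered_quantile"

    def test_transform_round_trip_on_reference_values(self, small_suite):
        _, suite = small_suite
        m = suite.models["SMAC"]
        assert m.pipeline.transform.kind == "ordered_quantile"
        back = invert_orq(m.pipeline.transform, m.reference_values)
        np.testing.assert_allclose(back, m.reference_raw, atol=1e-9)

    def test_summary_matches_models(self, small_suite):
        _, suite = small_suite
        summary = suite.summary()
        assert set(summary["platform"]) == {"HIC", "SMAC", "HEK"}
        assert (summary["mae"] >= 0).all()
        assert summary["r2"].between(0, 1).all()

    def test_skipped_platforms_listed(self, small_suite):
        _, suite = small_suite
        assert len(suite.skipped) == 9
        assert "ELISA" in suite.skipped

    def test_save_load_round_trip_bit_identical(self, small_suite, tmp_path):
        _, suite = small_suite
        probe = abdev.generate_fv(seed=77, n=1)[0]
        before = abdev.predict_platforms(suite, probe.fv)[0]
        path = tmp_path / "suite.json"
        save_suite(suite, path)
        loaded = load_suite(path)
        after = abdev.predict_platforms(loaded, probe.fv)[0]
        assert before == after
        assert loaded.models["HEK"].resolved_threshold == \
            suite.models["HEK"].resolved_threshold

    def test_truncated_file_is_parse_error(self, small_suite, tmp_path):
        _, suite = small_suite
        path = tmp_path / "suite.json"
        save_suite(suite, path)
        path.write_text(path.read_text()[:100])
        with pytest.raises(SuiteFormatError):
            load_suite(path)

    def test_version_mismatch_refused(self, small_suite, tmp_path):
        import json
        _, suite = small_suite
        path = tmp_path / "suite.json"
        save_suite(suite, path)
        doc = json.loads(path.read_text())
        doc["format_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(SuiteFormatError, match="99"):
            load_suite(path)
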