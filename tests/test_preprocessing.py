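import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abdev.errors import DegenerateDataError
from abdev.preprocessing import (aic_ols, apply_orq, apply_scaler,
                                 compute_vif, fit_orq, fit_scaler,
                                 invert_orq, invert_scaler, prune_collinear,
                                 stepwise_aic)


def oracle_vif(X: pd.DataFrame) -> pd.Series:
    """Independent brute-force VIF: per-feature OLS via statsmodels-free

    normal equations, 1/(1-R2)."""
    out = {}
    for col in X.columns:
        y = X[col].to_numpy()
        others = X.drop(columns=col).to_numpy()
        design = np.column_stack([np.ones(len(y)), others])
        beta = np.linalg.pinv(design.T @ design) @ design.T @ y
        rss = np.sum((y - design @ beta) ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        r2 = 1 - rss / tss
        out[col] = np.inf if r2 > 1 - 1e-12 else 1 / (1 - r2)
    return pd.Series(out)


class TestVif:
    def test_orthogonal_centered_features_have_unit_vif(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1], "b": [1, 1, -1, -1]},
                         dtype=float)
        vifs = compute_vif(X)
        assert vifs["a"] == pytest.approx(1.0)
        assert vifs["b"] == pytest.approx(1.0)

    def test_duplicated_feature_is_infinite(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        vifs = compute_vif(X)
        assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])

    def test_matches_bruteforce_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)),
                         columns=list("abcd"))
        X["d"] = X["a"] * 0.8 + rng.normal(size=50) * 0.3
        np.testing.assert_allclose(compute_vif(X).values,
                                   oracle_vif(X).values, rtol=1e-8)


class TestPruneCollinear:
    def test_clean_table_unchanged(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 5)),
                         columns=list("abcde"))
        sel = prune_collinear(X)
        assert sel.vif_all == list("abcde")
        assert sel.removal_log == []

    def test_duplicate_pair_loses_exactly_one(self, rng):
        x = rng.normal(size=40)
        X = pd.DataFrame({"a": x, "b": x + 0.0,
                          "c": rng.normal(size=40)})
        sel = prune_collinear(X)
        assert len(sel.vif_all) == 2
        assert "c" in sel.vif_all
        assert sel.vif_all.count("a") + sel.vif_all.count("b") == 1

    def test_tie_break_removes_later_column(self, rng):
        x = rng.normal(size=40)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=40)})
        sel = prune_collinear(X)
        assert sel.vif_all == ["a", "c"]
        assert sel.removal_log[0][0] == "b"

    def test_matches_greedy_oracle_on_planted_collinearity(self, rng):
        z = rng.normal(size=(80, 3))
        X = pd.DataFrame({
            "x1": z[:, 0],
            "x2": z[:, 1],
            "x3": z[:, 0] + 0.05 * rng.normal(size=80),
            "x4": z[:, 2],
            "x5": z[:, 1] - z[:, 0] + 0.05 * rng.normal(size=80),
            "x6": rng.normal(size=80),
        })
        # independent greedy loop with the brute-force VIF oracle
        cols = list(X.columns)
        while len(cols) >= 2:
            v = oracle_vif(X[cols])
            vmax = v.max()
            if not vmax >= 10:
                break
            tied = [c for c in cols if v[c] >= vmax - 1e-9]
            cols.remove(tied[-1])
        assert prune_collinear(X).vif_all == cols

    def test_terminates_with_all_vifs_below_threshold(self, rng):
        base = rng.normal(size=(50, 2))
        X = pd.DataFrame(
            np.column_stack([base, base @ rng.normal(size=(2, 4))
                             + 0.01 * rng.normal(size=(50, 4))]),
            columns=[f"x{i}" for i in range(6)],
        )
        sel = prune_collinear(X, threshold=10)
        final = compute_vif(X[sel.vif_all])
        assert (final < 10).all()


class TestStepwiseAic:
    def test_true_feature_selected_in_19_of_20_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(200, 6)),
                             columns=[f"x{i}" for i in range(6)])
            y = 3 * X["x0"] + rng.normal(size=200)
            sel = stepwise_aic(X, y)
            hits += "x0" in sel.vif_selected
        assert hits >= 19

    def test_optimum_start_returns_unchanged(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 3)),
                         columns=["a", "b", "c"])
        y = X["a"] + X["b"] + 0.05 * rng.normal(size=100)
        sel = stepwise_aic(X, y)
        # rerun starting from the found optimum: no move should improve
        again = stepwise_aic(X, y, start=sel.vif_selected)
        assert again.vif_selected == sel.vif_selected
        assert len(again.aic_log) == 1

    def test_aic_log_strictly_decreasing(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 6)),
                         columns=[f"x{i}" for i in range(6)])
        y = 2 * X["x1"] - X["x4"] + rng.normal(size=80)
        log = stepwise_aic(X, y).aic_log
        aics = [entry[-1] for entry in log]
        assert all(a > b for a, b in zip(aics, aics[1:]))

    def test_never_beats_exhaustive_search(self):
        agree = 0
        for seed in range(15):
            rng = np.random.default_rng(1000 + seed)
            k = 6
            X = pd.DataFrame(rng.normal(size=(60, k)),
                             columns=[f"x{i}" for i in range(k)])
            beta = rng.normal(size=k) * (rng.random(k) < 0.4)
            y = X.to_numpy() @ beta + rng.normal(size=60)
            greedy = stepwise_aic(X, y)
            greedy_aic = greedy.aic_log[-1][-1]
            best = min(
                aic_ols(X[list(sub)].to_numpy(), y)
                for r in range(k + 1)
                for sub in itertools.combinations(X.columns, r)
            )
            assert greedy_aic >= best - 1e-9
            agree += abs(greedy_aic - best) < 1e-9
        assert agree >= 12


class TestScaler:
    def test_closed_form(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        params = fit_scaler(X)
        np.testing.assert_allclose(apply_scaler(params, X)["a"],
                                   [-1.0, 0.0, 1.0])

    def test_new_row_equal_to_training_row(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        params = fit_scaler(X)
        row = X.iloc[[7]]
        np.testing.assert_allclose(apply_scaler(params, row).values,
                                   apply_scaler(params, X).iloc[[7]].values)

    def test_round_trip(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        params = fit_scaler(X)
        back = invert_scaler(params, apply_scaler(params, X))
        np.testing.assert_allclose(back.values, X.values, atol=1e-12)

    def test_zero_spread_feature_dropped(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10),
                          "flat": np.ones(10)})
        with pytest.warns(UserWarning, match="flat"):
            params = fit_scaler(X)
        assert params.features == ["a"]


class TestOrderedQuantile:
    def test_median_maps_to_zero_for_odd_n(self, rng):
        y = rng.normal(size=21)
        spec = fit_orq(y)
        assert apply_orq(spec, np.median(y)) == pytest.approx(0.0, abs=1e-12)

    def test_rank_preservation(self, rng):
        y = np.sort(rng.normal(size=25))
        z = apply_orq(fit_orq(y), y)
        assert np.all(np.diff(z) > 0)

    def test_round_trip_on_training_range(self, rng):
        y = rng.gumbel(size=40)
        spec = fit_orq(y)
        np.testing.assert_allclose(invert_orq(spec, apply_orq(spec, y)), y,
                                   atol=1e-9)

    def test_gumbel_sample_normalized(self):
        rng = np.random.default_rng(42)
        y = rng.gumbel(loc=10, scale=2, size=500)
        z = apply_orq(fit_orq(y), y)
        assert abs(z.mean()) < 0.1
        assert abs(z.std(ddof=1) - 1) < 0.15

    def test_out_of_range_extrapolates_monotonically(self, rng):
        y = rng.normal(size=30)
        spec = fit_orq(y)
        lo, hi = y.min(), y.max()
        assert apply_orq(spec, lo - 1) < apply_orq(spec, lo)
        assert apply_orq(spec, hi + 1) > apply_orq(spec, hi)

    def test_constant_response_refused(self):
        with pytest.raises(DegenerateDataError):
            fit_orq(np.ones(20))

    def test_too_few_values_refused(self):
        with pytest.raises(DegenerateDataError):
            fit_orq(np.arange(5.0))

    def test_normal_score_formula(self):
        """Training value with average rank r maps to Phi^-1((r-0.5)/n)."""
        y = np.array([3.0, 1.0, 2.0, 2.0, 5.0, 4.0, 6.0, 7.0, 8.0, 9.0])
        spec = fit_orq(y)
        ranks = stats.rankdata(y, method="average")
        expected = stats.norm.ppf((ranks - 0.5) / len(y))
        np.testing.assert_allclose(apply_orq(spec, y), expected, atol=1e-12)
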