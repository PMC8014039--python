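"""Stride features: statistics oracles, transforms, normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.regression.linear_model import yule_walker

from strideforge.features import (
    ANTHRO_NAMES,
    P_AUTO_BEST,
    P_MANUAL,
    P_MANUAL_BEST,
    STAT_NAMES,
    StrideFeatureTable,
    average_inputs,
    channel_statistics,
    linearize,
    robust_normalize,
)


def brute_force_stats(x: np.ndarray) -> dict:
    """Independent single-channel implementation of the 11 statistics."""
    out = {
        "mean": np.mean(x),
        "std": np.std(x, ddof=1),
        "median": np.median(x),
        "iqr": np.percentile(x, 75) - np.percentile(x, 25),
        "max": np.max(x),
        "rms": np.sqrt(np.mean(x**2)),
        "kurt": sps.kurtosis(x, fisher=False, bias=True),
        "skew": sps.skew(x, bias=True),
    }
    rho, _ = yule_walker(x - x.mean(), order=3, method="mle")
    out["arm1"], out["arm2"], out["arm3"] = rho
    return out


class TestChannelStatistics:
    def test_small_window_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
        stats, flags = channel_statistics(x[:, None])
        named = dict(zip(STAT_NAMES, stats[:, 0]))
        assert named["mean"] == pytest.approx(2.5)
        assert named["max"] == pytest.approx(4.0)
        assert named["rms"] == pytest.approx(np.sqrt(7.5))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_windows(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(rng.integers(20, 400), 3))
        stats, _ = channel_statistics(x)
        for j in range(3):
            expected = brute_force_stats(x[:, j])
            for k, name in enumerate(STAT_NAMES):
                assert stats[k, j] == pytest.approx(expected[name], abs=1e-10), name

    def test_gaussian_shape_statistics_conventions(self):
        # Pearson (non-excess) kurtosis -> 3 for a Gaussian; biased skewness -> 0
        rng = np.random.default_rng(12)
        x = rng.standard_normal(100_000)[:, None]
        stats, _ = channel_statistics(x)
        named = dict(zip(STAT_NAMES, stats[:, 0]))
        assert abs(named["skew"]) < 0.03
        assert abs(named["kurt"] - 3.0) < 0.06

    def test_ar3_recovers_planted_coefficients(self):
        rng = np.random.default_rng(3)
        true = np.array([0.5, -0.3, 0.2])
        n = 10_000
        x = np.zeros(n)
        eps = rng.normal(0, 1.0, n)
        for t in range(3, n):
            x[t] = true @ x[[t - 1, t - 2, t - 3]] + eps[t]
        stats, _ = channel_statistics(x[:, None])
        est = stats[8:11, 0]
        assert np.abs(est - true).max() < 0.05

    def test_constant_window_flagged_with_zero_shape_stats(self):
        stats, flags = channel_statistics(np.full((50, 1), 2.0))
        named = dict(zip(STAT_NAMES, stats[:, 0]))
        assert flags[0]
        assert named["kurt"] == 0.0 and named["skew"] == 0.0
        assert named["std"] == 0.0

    def test_too_short_window_raises(self):
        with pytest.raises(ValueError, match="8"):
            channel_statistics(np.zeros((5, 1)))


class TestLinearize:
    def test_worked_example(self):
        df = pd.DataFrame({"p": [2.0]})
        out, cols = linearize(df, ["p"])
        assert out["f1(p)"].iloc[0] == 4.0
        assert out["f2(p)"].iloc[0] == 8.0
        assert out["f3(p)"].iloc[0] == 0.5

    def test_width_quadruples(self):
        rng = np.random.default_rng(0)
        base = [f"c{i}" for i in range(7)]
        df = pd.DataFrame(rng.normal(size=(20, 7)), columns=base)
        out, cols = linearize(df, base)
        assert len(cols) == 4 * len(base)

    def test_inverse_of_zero_masked_not_propagated(self):
        df = pd.DataFrame({"p": [0.0, 2.0]})
        out, _ = linearize(df, ["p"])
        assert np.isnan(out["f3(p)"].iloc[0])
        assert out["f3(p)"].iloc[1] == 0.5

    def test_square_of_inverse_equals_inverse_of_square(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"p": rng.uniform(0.5, 3.0, 50)})
        out, _ = linearize(df, ["p"])
        lhs = out["f3(p)"] ** 2
        rhs = 1.0 / out["f1(p)"]
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestRobustNormalize:
    def test_mean_zero_mad_one(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
        out, stats = robust_normalize(df, ["a"])
        assert out["a"].mean() == pytest.approx(0.0, abs=1e-12)
        centered = out["a"] - out["a"].median()
        assert centered.abs().median() == pytest.approx(1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(3.0, 2.0, 200)})
        once, _ = robust_normalize(df, ["a"])
        twice, _ = robust_normalize(once, ["a"])
        assert np.abs(twice["a"] - once["a"]).max() < 1e-10

    def test_scale_robust_to_single_outlier(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 1.0, 501)
        with_outlier = x.copy()
        with_outlier[0] = 1e6
        clean = x.copy()
        clean[0] = np.median(x)
        _, s1 = robust_normalize(pd.DataFrame({"a": with_outlier}), ["a"])
        _, s2 = robust_normalize(pd.DataFrame({"a": clean}), ["a"])
        assert s1.loc["a", "mad"] == pytest.approx(s2.loc["a", "mad"], rel=0.02)

    def test_train_stats_applied_to_test_without_refit(self):
        rng = np.random.default_rng(3)
        train = pd.DataFrame({"a": rng.normal(0.0, 1.0, 300)})
        test = pd.DataFrame({"a": rng.normal(5.0, 1.0, 300)})  # shifted
        _, train_stats = robust_normalize(train, ["a"])
        test_norm, applied = robust_normalize(test, ["a"], stats=train_stats)
        _, refit = robust_normalize(test, ["a"])
        assert applied.loc["a", "mean"] == train_stats.loc["a", "mean"]
        assert refit.loc["a", "mean"] != pytest.approx(train_stats.loc["a", "mean"])
        # a shifted test distribution stays shifted under train stats
        assert test_norm["a"].mean() > 3.0

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": np.ones(10)})
        _, stats = robust_normalize(df, ["a"])
        assert not stats.loc["a", "usable"]


class TestAverageInputs:
    def _table(self, values, label=None):
        n = len(values)
        df = pd.DataFrame({
            "f": values, "label": label if label is not None else np.ones(n),
            "ic": np.arange(n, dtype=float), "subject": "S00", "foot": "left",
        })
        return StrideFeatureTable(df=df, feature_cols=["f"])

    def test_pairwise_mean(self):
        out = average_inputs(self._table([1.0, 3.0]), 2)
        assert out.df["f"].iloc[0] == 2.0

    def test_constant_table_unchanged_values(self):
        out = average_inputs(self._table([2.0] * 11), 4)
        assert np.allclose(out.df["f"], 2.0)
        assert len(out.df) == 2  # floor(11/4), trailing partial dropped

    def test_blocks_match_brute_force_group_means(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=23)
        out = average_inputs(self._table(vals), 4)
        for b in range(5):
            assert out.df["f"].iloc[b] == pytest.approx(vals[4 * b : 4 * b + 4].mean())

    def test_odd_k_rejected(self):
        with pytest.raises(ValueError, match="even"):
            average_inputs(self._table([1.0, 2.0, 3.0]), 3)

    def test_k1_identity(self):
        table = self._table([1.0, 2.0, 3.0])
        assert average_inputs(table, 1) is table


class TestEndToEndFeatures:
    def test_constant_speed_labels(self, processed_clean):
        labels = processed_clean.feature_table.labels()
        assert np.abs(labels - 3.0).max() < 1e-6

    def test_candidate_feature_count_audited(self, processed_clean):
        ft = processed_clean.feature_table
        # 11 stats x 13 channels + 5 temporal + pitch = 149 base features,
        # quadrupled by the transforms, plus 4 anthropometrics
        assert ft.meta["n_base_features"] == 149
        assert len(ft.feature_cols) == 4 * 149 + 4

    def test_presets_are_subsets_of_the_table(self, processed_clean):
        cols = set(processed_clean.feature_table.feature_cols)
        for preset in (P_MANUAL, P_AUTO_BEST, P_MANUAL_BEST):
            assert set(preset) <= cols

    def test_norm_mean_bounds_component_means(self, processed_clean):
        df = processed_clean.feature_table.df
        for ch in ("x", "y", "z"):
            assert np.all(
                df["mean_vfoot_norm"] >= df[f"mean_vfoot_{ch}"].abs() - 1e-9
            )

    def test_rms_squared_bounds_mean_squared(self, processed_clean):
        df = processed_clean.feature_table.df
        for col in ("a_x", "a_norm", "omega_z", "vfoot_norm"):
            assert np.all(df[f"rms_{col}"] ** 2 >= df[f"mean_{col}"] ** 2 - 1e-9)

    def test_anthropometrics_present(self, processed_clean):
        df = processed_clean.feature_table.df
        for name in ANTHRO_NAMES:
            assert df[name].nunique() == 1
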