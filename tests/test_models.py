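"""Generic linear model: RUS, stepwise selection, LASSO, LOSO harness."""

import numpy as np
import pandas as pd
import pytest

from strideforge.features import P_AUTO_BEST, P_MANUAL, P_MANUAL_BEST, StrideFeatureTable
from strideforge.models import (
    RUS_BIN_EDGES,
    LinearSpeedModel,
    forward_stepwise_select,
    loso_harness,
    moving_average_output,
    random_undersample,
)


class TestRUS:
    def _labels(self, counts):
        rng = np.random.default_rng(0)
        parts = [rng.uniform(RUS_BIN_EDGES[b], RUS_BIN_EDGES[b + 1] - 1e-6, c)
                 for b, c in enumerate(counts)]
        return np.concatenate(parts)

    def test_min_rule(self):
        plan = random_undersample(self._labels([100, 50, 80, 60, 50]), seed=1)
        assert [len(r) for r in plan.retained] == [50] * 5

    def test_already_balanced_keeps_everything(self):
        labels = self._labels([40, 40, 40, 40, 40])
        plan = random_undersample(labels, seed=2)
        assert plan.indices.size == 200
        assert np.array_equal(plan.indices, np.arange(200))

    def test_deterministic_under_seed(self):
        labels = self._labels([100, 50, 80, 60, 50])
        p1 = random_undersample(labels, seed=9)
        p2 = random_undersample(labels, seed=9)
        assert np.array_equal(p1.indices, p2.indices)

    def test_out_of_range_labels_excluded(self):
        labels = np.concatenate([self._labels([30, 30, 30, 30, 30]), [0.5, 6.0]])
        plan = random_undersample(labels, seed=3)
        assert plan.n_excluded == 2
        assert plan.indices.size == 150

    def test_equal_bin_counts_hard_assert(self):
        rng = np.random.default_rng(7)
        labels = rng.uniform(1.4, 5.39, 500)
        plan = random_undersample(labels, seed=4)
        counts = {len(r) for r in plan.retained}
        assert len(counts) == 1


class TestStepwise:
    def _table(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"p{i}" for i in range(6)])
        subjects = np.repeat([f"S{i}" for i in range(4)], n // 4)
        return X, subjects, rng

    def test_perfect_predictor_selected_first_then_stop(self):
        X, subjects, rng = self._table()
        # nonlinear target: no single raw column predicts it, only the copy
        y = 2.0 * X["p1"].to_numpy() * X["p2"].to_numpy() + np.sin(X["p3"].to_numpy())
        X["copy_of_label"] = y
        selected, trace = forward_stepwise_select(X, y, subjects)
        assert selected[0] == "copy_of_label"
        assert len(selected) == 1
        assert trace[0] < 1e-20

    @pytest.mark.parametrize("seed", range(5))
    def test_first_pick_matches_exhaustive_single_feature_search(self, seed):
        X, subjects, rng = self._table(seed=seed)
        beta = rng.normal(size=6)
        y = X.to_numpy() @ beta + rng.normal(0, 0.5, len(X))
        selected, _ = forward_stepwise_select(X, y, subjects, max_features=1)
        # brute force: LOSO OLS MSE of each single feature
        best, best_mse = None, np.inf
        for c in X.columns:
            mses = []
            for s in np.unique(subjects):
                tr, te = subjects != s, subjects == s
                A = np.column_stack([np.ones(tr.sum()), X.loc[tr, c]])
                coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
                pred = np.column_stack([np.ones(te.sum()), X.loc[te, c]]) @ coef
                mses.append(np.mean((pred - y[te]) ** 2))
            if np.mean(mses) < best_mse:
                best, best_mse = c, np.mean(mses)
        assert selected[0] == best

    def test_planted_structure_beats_noise_columns(self):
        # label = 2 p1 - p3^2 + eps: p1 and f1(p3) should precede pure noise
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 240
            X = pd.DataFrame(rng.normal(size=(n, 5)),
                             columns=["p1", "p2", "p3", "p4", "p5"])
            y = 2 * X["p1"].to_numpy() - X["p3"].to_numpy() ** 2 + rng.normal(0, 0.1, n)
            X["f1(p1)"] = X["p1"] ** 2
            X["f1(p3)"] = X["p3"] ** 2
            subjects = np.repeat([f"S{i}" for i in range(4)], n // 4)
            selected, _ = forward_stepwise_select(X, y, subjects, max_features=4)
            informative = {"p1", "f1(p3)"}
            noise_cols = {"p2", "p4", "p5"}
            first_noise = next((i for i, c in enumerate(selected) if c in noise_cols),
                               len(selected))
            if informative <= set(selected[:first_noise]):
                hits += 1
        assert hits >= 19  # >= 95 % of 20 seeds

    def test_needs_two_subjects(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError, match="2 development subjects"):
            forward_stepwise_select(X, np.arange(10.0), np.array(["S0"] * 10))


class TestLasso:
    def _fixture(self, n=300, p=4, seed=0, noise=0.05):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        beta = np.array([1.0, -0.5, 0.25, 0.8])[:p]
        y = 3.0 + X @ beta + rng.normal(0, noise, n)
        df = pd.DataFrame(X, columns=[f"p{i}" for i in range(p)])
        df["label"] = y
        df["subject"] = "S0"
        df["ic"] = np.arange(n, dtype=float)
        return df, beta

    def test_small_penalty_limit_matches_ols(self):
        df, beta = self._fixture(noise=0.0)
        model = LinearSpeedModel(df, [f"p{i}" for i in range(4)])
        res = model.fit(n_alphas=120, eps=1e-10, tol=1e-12)
        # exact linear label: the path end reproduces OLS on standardized X
        X = df[[f"p{i}" for i in range(4)]].to_numpy()
        Z = (X - X.mean(0)) / X.std(0)
        ols = np.linalg.lstsq(np.column_stack([np.ones(len(Z)), Z]),
                              df["label"].to_numpy(), rcond=None)[0]
        assert np.abs(res.coef - ols[1:]).max() < 1e-6
        pred = res.predict(df)
        assert np.abs(pred - df["label"].to_numpy()).max() < 1e-5

    def test_label_independent_of_features_gives_intercept_only(self):
        rng = np.random.default_rng(1)
        df, _ = self._fixture()
        df["label"] = 3.0 + rng.normal(0, 0.01, len(df)) * 0  # constant label
        model = LinearSpeedModel(df, [f"p{i}" for i in range(4)])
        res = model.fit()
        assert res.selected_features == []
        assert res.predict(df) == pytest.approx(3.0)

    def test_duplicate_column_gets_single_weight_at_sparse_solutions(self):
        # label depends on one predictor duplicated in the pool: the sparse
        # model the size rule picks carries weight on only one of the pair
        rng = np.random.default_rng(4)
        n = 400
        x0 = rng.normal(size=n)
        df = pd.DataFrame({
            "p0": x0, "p_dup": x0, "label": 3.0 + 2 * x0 + rng.normal(0, 0.2, n),
            "subject": "S0", "ic": np.arange(n, dtype=float),
        })
        res = LinearSpeedModel(df, ["p0", "p_dup"]).fit()
        assert len(res.selected_features) == 1

    def test_size_rule_prefers_sparser_model(self):
        # one strong predictor + one nearly-irrelevant one: the 2 % rule
        # must stop at the single-input model
        rng = np.random.default_rng(2)
        n = 400
        x0 = rng.normal(size=n)
        x1 = rng.normal(size=n)
        y = 3.0 + 1.0 * x0 + 0.001 * x1 + rng.normal(0, 0.2, n)
        df = pd.DataFrame({"p0": x0, "p1": x1, "label": y, "subject": "S0",
                           "ic": np.arange(n, dtype=float)})
        res = LinearSpeedModel(df, ["p0", "p1"]).fit()
        assert res.selected_features == ["p0"]


class TestPrediction:
    def test_zero_standardized_features_give_intercept(self):
        df = pd.DataFrame({"p0": np.zeros(5), "label": np.full(5, 2.0)})
        from strideforge.models import LinearSpeedResults
        res = LinearSpeedResults(
            features=["p0"], coef=np.array([0.7]), intercept=2.5,
            x_mean=np.zeros(1), x_std=np.ones(1), alpha=0.1, train_mse=0.0,
            n_train=5,
        )
        assert res.predict(df) == pytest.approx(2.5)

    def test_output_averaging_k1_identity(self):
        v = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(moving_average_output(v, 1), v)

    def test_output_averaging_preserves_constants(self):
        v = np.full(11, 2.5)
        assert np.allclose(moving_average_output(v, 4), 2.5)


class TestLosoHarness:
    def _cohort_table(self, n_subjects=4, n_steps=120, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            v = rng.uniform(1.5, 5.3, n_steps)
            rows.append(pd.DataFrame({
                "subject": f"S{s:02d}", "ic": np.arange(n_steps, dtype=float),
                "p0": v + rng.normal(0, 0.1, n_steps),
                "p1": rng.normal(size=n_steps),
                "label": v,
            }))
        df = pd.concat(rows, ignore_index=True)
        return StrideFeatureTable(df=df, feature_cols=["p0", "p1"])

    def test_one_prediction_set_per_pool_subject(self):
        table = self._cohort_table()
        preds = loso_harness(table, ["p0", "p1"], n_repetitions=2, master_seed=1)
        assert set(preds.subject) == set(table.df.subject)
        assert set(preds.repetition) == {0, 1}

    def test_dev_pool_overlap_is_hard_error(self):
        table = self._cohort_table()
        with pytest.raises(ValueError, match="both development and pool"):
            loso_harness(table, ["p0"], dev_subjects=["S01"])

    def test_held_out_labels_never_influence_training(self):
        # corrupting one subject's labels must not change that subject's
        # predictions: its rows (and labels) are excluded from every stage
        # of its own fold
        table = self._cohort_table(seed=3)
        preds1 = loso_harness(table, ["p0", "p1"], n_repetitions=1, master_seed=5)
        corrupted = table.df.copy()
        mask = corrupted.subject == "S02"
        corrupted.loc[mask, "label"] = 99.0
        table2 = StrideFeatureTable(df=corrupted, feature_cols=["p0", "p1"])
        preds2 = loso_harness(table2, ["p0", "p1"], n_repetitions=1, master_seed=5)
        a = preds1[preds1.subject == "S02"].pred.to_numpy()
        b = preds2[preds2.subject == "S02"].pred.to_numpy()
        assert np.array_equal(a, b)


class TestPresets:
    def test_comprehensive_feature_list(self):
        assert P_MANUAL == ["height", "CT", "FLT", "STR", "mean_vfoot_norm",
                            "max_omega_z", "rms_omega_norm", "max_a_norm", "mean_s"]

    def test_best_presets_sizes(self):
        assert len(P_AUTO_BEST) == 7
        assert len(P_MANUAL_BEST) == 4
        assert set(P_MANUAL_BEST) == {"rms_omega_norm", "mean_vfoot_norm",
                                      "mean_s", "CT"}
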