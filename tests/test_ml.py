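import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synores import (
    FilterSpec,
    FittedResponseModel,
    ModelSpec,
    aggregate_importance,
    evaluate,
    external_validate,
    fit_final,
    make_fold_plan,
    nested_cv,
    ordinal_encode_outcome,
    ordinal_to_binary,
    sparse_embedded_filter,
    ttest_filter,
    tune_inner,
)


def _check_plan(plan, y):
    n = len(y)
    y = np.asarray(y)
    for r in range(plan.repeats):
        outer = plan.outer[r]
        assert sorted(np.unique(outer)) == list(range(plan.outer_k))
        # outer folds partition all samples
        assert len(outer) == n
        sizes = np.bincount(outer)
        assert sizes.max() - sizes.min() <= len(np.unique(y))
        if plan.stratified:
            for cls in np.unique(y):
                counts = np.bincount(outer[y == cls], minlength=plan.outer_k)
                assert counts.max() - counts.min() <= 1
        for f in range(plan.outer_k):
            inner = plan.inner[(r, f)]
            train = outer != f
            assert (inner[~train] == -1).all()
            assert (inner[train] >= 0).all()
            assert sorted(np.unique(inner[train])) == list(range(plan.inner_k))


class TestFoldPlan:
    def test_balanced_partition_and_nesting(self):
        y = np.array([0] * 70 + [1] * 30)
        plan = make_fold_plan(y, outer_k=10, inner_k=5, repeats=3, seed=0)
        _check_plan(plan, y)

    def test_stratification_bounds(self):
        y = np.array([0] * 70 + [1] * 30)
        plan = make_fold_plan(y, outer_k=10, inner_k=5, repeats=2, seed=1)
        for outer in plan.outer:
            for f in range(10):
                assert abs((y[outer == f] == 1).sum() - 3) <= 1

    def test_deterministic_given_seed(self):
        y = np.array([0, 1] * 20)
        a = make_fold_plan(y, 5, 3, repeats=2, seed=7)
        b = make_fold_plan(y, 5, 3, repeats=2, seed=7)
        assert all(np.array_equal(x, z) for x, z in zip(a.outer, b.outer))

    def test_minority_class_too_small(self):
        y = np.array([0] * 50 + [1] * 5)
        with pytest.raises(ValueError, match="fewer folds"):
            make_fold_plan(y, outer_k=10, inner_k=5, repeats=1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_invariants_hold_for_random_seeds(self, seed):
        rng = np.random.default_rng(seed % 10_000)
        n = int(rng.integers(30, 80))
        y = rng.integers(0, 2, n)
        k = 3
        if min((y == 0).sum(), (y == 1).sum()) < k:
            y[: k + 1] = 0
            y[k + 1 : 2 * (k + 1)] = 1
        plan = make_fold_plan(y, outer_k=k, inner_k=2, repeats=1, seed=seed)
        _check_plan(plan, y)


class TestFilters:
    def test_perfect_separator_ranked_first(self, rng):
        y = np.array([0] * 10 + [1] * 10, dtype=float)
        X = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        X["sep"] = y * 10
        assert ttest_filter(X, y, 1) == ["sep"]

    def test_identity_when_keeping_all(self, rng):
        y = np.array([0, 1] * 10, dtype=float)
        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        assert sorted(ttest_filter(X, y, 4)) == list("abcd")
        with pytest.raises(ValueError):
            ttest_filter(X, y, 5)

    def test_pure_noise_selection_is_near_uniform(self, rng):
        counts = {}
        y = np.array([0] * 15 + [1] * 15, dtype=float)
        for _ in range(300):
            X = pd.DataFrame(rng.normal(size=(30, 20)))
            for f in ttest_filter(X, y, 2):
                counts[f] = counts.get(f, 0) + 1
        freq = np.array([counts.get(j, 0) for j in range(20)]) / 600
        assert freq.max() < 3.0 / 20  # no feature dominates

    def test_sparse_filter_single_informative(self, rng):
        n = 200
        x0 = rng.normal(size=n)
        y = (x0 > 0).astype(float)
        X = pd.DataFrame(
            np.column_stack([x0, rng.normal(size=(n, 10))]),
            columns=[f"f{j}" for j in range(11)],
        )
        spec = FilterSpec(method="sparse_embedded", penalty_grid=(0.3,), size_bounds=(1, 1))
        kept = sparse_embedded_filter(X, y, spec)
        assert kept == ["f0"]

    def test_sparse_filter_zero_penalty_keeps_all(self, rng):
        y = np.array([0, 1] * 20, dtype=float)
        X = pd.DataFrame(rng.normal(size=(40, 6)), columns=[f"f{j}" for j in range(6)])
        spec = FilterSpec(
            method="sparse_embedded", penalty_grid=(0.0,), size_bounds=(6, 6), l1_ratio=1.0
        )
        assert len(sparse_embedded_filter(X, y, spec)) == 6

    def test_sparse_filter_falls_back_on_empty(self, rng):
        y = np.array([0, 1] * 20, dtype=float)
        X = pd.DataFrame(rng.normal(size=(40, 6)), columns=[f"f{j}" for j in range(6)])
        spec = FilterSpec(
            method="sparse_embedded", penalty_grid=(50.0,), size_bounds=(2, 3), n_keep=2
        )
        with pytest.warns(UserWarning, match="falling back"):
            kept = sparse_embedded_filter(X, y, spec)
        assert len(kept) == 2


class TestTuning:
    def test_single_grid_point_returned(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40).astype(float)
        inner = np.array(([0] * 20 + [1] * 20))
        spec = ModelSpec(grid=({"alpha": 0.7},))
        assert tune_inner(spec, X, y, inner) == {"alpha": 0.7}

    def test_small_penalty_beats_huge_on_separable_data(self, rng):
        x = np.linspace(-2, 2, 60)
        y = (x > 0).astype(float)
        X = np.column_stack([x, rng.normal(size=60)])
        inner = np.tile([0, 1, 2], 20)
        spec = ModelSpec(grid=({"alpha": 100.0}, {"alpha": 0.01}))
        assert tune_inner(spec, X, y, inner) == {"alpha": 0.01}


class TestOutcomeCoding:
    @pytest.mark.parametrize(
        "das28,level,resp",
        [
            (2.5, "remission", True),
            (2.9, "low", True),
            (3.2, "moderate", False),
            (5.1, "moderate", False),
            (5.2, "high", False),
        ],
    )
    def test_band_edges(self, das28, level, resp):
        levels, codes = ordinal_encode_outcome([das28])
        assert levels[0] == level
        assert (codes[0] <= 1) == resp

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ordinal_encode_outcome([-0.1])

    def test_ordinal_to_binary_midpoint_and_monotonicity(self):
        score, label = ordinal_to_binary([0.2, 1.5, 2.9])
        assert label.tolist() == [1, 0, 0]
        assert score[1] == 0.5
        assert (np.diff(score) < 0).all()

    def test_rank_invariance_of_auc(self, rng):
        pred = rng.normal(1.5, 1.0, 100)
        y = (pred + rng.normal(0, 1, 100) < 1.5).astype(float)
        score, _ = ordinal_to_binary(pred)
        assert np.isclose(
            evaluate(score, y)["auc"], evaluate(-pred, y)["auc"]
        )


class TestEvaluate:
    def test_perfect_and_constant_scores(self):
        assert evaluate([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])["auc"] == 1.0
        assert evaluate([0.5] * 6, [1, 0, 1, 0, 1, 0])["auc"] == 0.5

    def test_known_pair_counting_example(self):
        out = evaluate([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0])
        assert out["auc"] == 0.75

    def test_matches_brute_force_concordance(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 200))
            s = np.round(rng.random(n), 2)  # rounded -> ties exercised
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            auc = evaluate(s, y)["auc"]
            pos = s[y == 1]
            neg = s[y == 0]
            wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
                pos[:, None] == neg[None, :]
            ).sum()
            assert np.isclose(auc, wins / (len(pos) * len(neg)), rtol=1e-12)

    def test_single_class_auc_missing(self):
        assert np.isnan(evaluate([0.4, 0.6], [1, 1])["auc"])

    def test_balanced_accuracy_definition(self):
        out = evaluate([0.9, 0.9, 0.9, 0.1], [1, 0, 1, 0])
        # sens = 1, spec = 0.5
        assert out["balanced_accuracy"] == 0.75


@pytest.fixture(scope="module")
def signal_data():
    rng = np.random.default_rng(77)
    n, G = 120, 150
    u = rng.normal(size=n)
    y = (rng.random(n) < 1 / (1 + np.exp(-2.2 * u))).astype(float)
    X = pd.DataFrame(
        rng.normal(size=(n, G)) * 0.6,
        columns=[f"g{j}" for j in range(G)],
        index=[f"s{i}" for i in range(n)],
    )
    for j in range(15):
        X[f"g{j}"] += u
    clinical = pd.DataFrame(
        {"logCRP": rng.normal(size=n)}, index=X.index
    )
    return X, y, clinical


class TestNestedCV:
    def test_each_sample_predicted_once_per_repeat(self, signal_data):
        X, y, clinical = signal_data
        plan = make_fold_plan(y, outer_k=4, inner_k=3, repeats=2, seed=2)
        res = nested_cv(X, y, clinical, FilterSpec(n_keep=10), ModelSpec(), plan)
        for r, grp in res.predictions.groupby("repeat"):
            assert sorted(grp["sample"]) == sorted(X.index)

    def test_signal_is_detected(self, signal_data):
        X, y, clinical = signal_data
        plan = make_fold_plan(y, outer_k=4, inner_k=3, repeats=2, seed=3)
        res = nested_cv(X, y, clinical, FilterSpec(n_keep=10), ModelSpec(), plan)
        assert res.metrics["auc"].mean() > 0.7

    def test_ordinal_mode_reports_r_squared(self, rng):
        n = 100
        u = rng.normal(size=n)
        codes = np.clip(np.round(1.5 + u), 0, 3)
        X = pd.DataFrame(
            np.column_stack([u + 0.2 * rng.normal(size=n), rng.normal(size=(n, 20))]),
            columns=[f"g{j}" for j in range(21)],
        )
        spec = ModelSpec(
            learner="ordinal_linear",
            grid=({"alpha": 1.0}, {"alpha": 10.0}),
            outcome="ordinal4",
            metric="r_squared",
        )
        plan = make_fold_plan((codes <= 1).astype(int), outer_k=4, inner_k=3, repeats=1, seed=4)
        res = nested_cv(X, codes, None, FilterSpec(n_keep=5), spec, plan)
        assert res.metrics["r_squared"].iloc[0] > 0.3
        assert res.metrics["auc"].iloc[0] > 0.8

    def test_model_spec_mode_constraints(self):
        with pytest.raises(ValueError):
            ModelSpec(metric="r_squared", outcome="binary")
        with pytest.raises(ValueError):
            ModelSpec(outcome="ordinal4", metric="log_loss")


class TestImportanceAggregation:
    def test_constant_importance_and_absent_predictor(self):
        records = [
            {"importance": {"a": 2.0, "b": 1.0}},
            {"importance": {"a": 2.0}},
        ]
        table = aggregate_importance(records)
        assert table.loc["a", "mean_importance"] == 2.0
        assert table.loc["a", "se_importance"] == 0.0
        assert table.loc["a", "frequency"] == 1.0
        assert table.loc["b", "frequency"] == 0.5
        assert "never_selected" not in table.index


class TestFinalModel:
    def test_serialisation_roundtrip_predictions(self, signal_data, tmp_path):
        X, y, clinical = signal_data
        model = fit_final(X, y, clinical, FilterSpec(n_keep=10), ModelSpec(), inner_k=3, seed=5, drug="etanercept")
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = FittedResponseModel.from_json(path)
        feats = pd.concat([X, clinical], axis=1)
        assert np.allclose(model.predict_proba(feats), loaded.predict_proba(feats))

    def test_gbt_serialisation_roundtrip(self, signal_data):
        X, y, clinical = signal_data
        spec = ModelSpec(
            learner="gradient_boosted_trees",
            grid=({"n_estimators": 20, "random_state": 0},),
        )
        model = fit_final(X, y, clinical, FilterSpec(n_keep=8), spec, inner_k=3, seed=6)
        loaded = FittedResponseModel.from_json(model.to_json())
        feats = pd.concat([X, clinical], axis=1)
        assert np.allclose(model.predict_proba(feats), loaded.predict_proba(feats))

    def test_training_auc_at_least_nested(self, signal_data):
        X, y, clinical = signal_data
        plan = make_fold_plan(y, outer_k=4, inner_k=3, repeats=1, seed=8)
        nested = nested_cv(X, y, clinical, FilterSpec(n_keep=10), ModelSpec(), plan)
        model = fit_final(X, y, clinical, FilterSpec(n_keep=10), ModelSpec(), inner_k=3, seed=8)
        feats = pd.concat([X, clinical], axis=1)
        train_auc = evaluate(model.predict_proba(feats).to_numpy(), y)["auc"]
        assert train_auc >= nested.metrics["auc"].iloc[0] - 0.02  # optimism

    def test_missing_predictor_named(self, signal_data):
        X, y, clinical = signal_data
        model = fit_final(X, y, clinical, FilterSpec(n_keep=5), ModelSpec(), inner_k=3, seed=9)
        gene = model.gene_predictors[0]
        X2 = X.drop(columns=[gene])
        with pytest.raises(KeyError, match=gene):
            external_validate(model, X2, clinical, y)

    def test_external_validation_close_to_nested(self):
        rng = np.random.default_rng(3)

        def cohort(seed):
            r = np.random.default_rng(seed)
            n = 150
            u = r.normal(size=n)
            y = (r.random(n) < 1 / (1 + np.exp(-2.2 * u))).astype(float)
            X = pd.DataFrame(
                r.normal(size=(n, 60)) * 0.6, columns=[f"g{j}" for j in range(60)]
            )
            for j in range(10):
                X[f"g{j}"] += u
            return X, y

        X, y = cohort(1)
        X2, y2 = cohort(2)
        plan = make_fold_plan(y, outer_k=5, inner_k=3, repeats=2, seed=0)
        nested = nested_cv(X, y, None, FilterSpec(n_keep=10), ModelSpec(), plan)
        model = fit_final(X, y, None, FilterSpec(n_keep=10), ModelSpec(), inner_k=3, seed=0)
        out = external_validate(model, X2, None, y2)
        assert abs(out["auc"] - nested.metrics["auc"].mean()) < 0.1
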