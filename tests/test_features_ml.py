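import math

import numpy as np
import pandas as pd
import pytest

from adrsignal.ehr_model import DrugLabEvent, ReferencePair
from adrsignal.extraction import ExtractionContext
from adrsignal.features_ml import (
    FEATURE_NAMES,
    EvalMetrics,
    ModelSpec,
    assemble_features,
    compare_auroc,
    comparator_decisions,
    comparator_evaluation,
    evaluate,
    extract_pair_features,
    feature_importance,
    make_model,
    minmax_scale_labs,
    predict_signal,
    repeated_cv_evaluation,
    standardize_features,
    tune_and_train,
)

from conftest import toy_cohort


class TestMinMaxScaling:
    def test_formula(self):
        cohort = toy_cohort(
            [{"visit_id": "v1", "stay": 3}],
            [{"visit_id": "v1", "day": d, "value": v} for d, v in enumerate([0, 5, 10])],
            [],
        )
        scaled = minmax_scale_labs(cohort)
        assert list(scaled.measurement["scaled_value"]) == [0.0, 0.5, 1.0]

    def test_constant_lab_maps_to_half_with_warning(self):
        cohort = toy_cohort(
            [{"visit_id": "v1", "stay": 2}],
            [{"visit_id": "v1", "day": d, "value": 3.0} for d in range(2)],
            [],
        )
        with pytest.warns(UserWarning, match="constant"):
            scaled = minmax_scale_labs(cohort)
        assert (scaled.measurement["scaled_value"] == 0.5).all()

    def test_output_in_unit_interval_per_lab(self, null_sim):
        _, cohort, ctx = null_sim
        s = ctx.cohort.measurement["scaled_value"]
        assert s.min() >= 0.0 and s.max() <= 1.0
        g = ctx.cohort.measurement.groupby("lab_code")["scaled_value"]
        assert (g.min() == 0.0).all() and (g.max() == 1.0).all()


@pytest.fixture(scope="module")
def small_extraction(planted_sim):
    _, cohort, ctx, adr, ind = planted_sim
    pairs = [
        adr,
        ind,
        DrugLabEvent("D0003", "L003", "increased"),
        DrugLabEvent("D0004", "L004", "decreased"),
        DrugLabEvent("D0005", "L000", "increased"),
        DrugLabEvent("D0006", "L001", "decreased"),
        DrugLabEvent("D0007", "L002", "increased"),
        DrugLabEvent("D0008", "L003", "decreased"),
        DrugLabEvent("D0009", "L004", "increased"),
        DrugLabEvent("D0000", "L005", "decreased"),
    ]
    reference = [ReferencePair(p, 1 if p == adr else 0) for p in pairs]
    extractions = extract_pair_features(ctx, pairs, seed=3)
    return extractions, reference


class TestAssembleFeatures:
    def test_48_columns_in_canonical_order(self, small_extraction):
        extractions, reference = small_extraction
        raw, mask, y = assemble_features(extractions, reference)
        assert list(raw.columns) == FEATURE_NAMES
        assert raw.shape == (len(reference), 48)
        assert y.sum() == 1

    def test_standardized_columns_have_zero_mean_unit_sd(self, small_extraction):
        extractions, reference = small_extraction
        raw, mask, _ = assemble_features(extractions, reference)
        X = standardize_features(raw)
        filled = ~mask.to_numpy()
        for j, col in enumerate(FEATURE_NAMES):
            vals = X.to_numpy()[filled[:, j], j]
            if len(vals) > 1 and raw[col].std(ddof=0) > 0:
                assert abs(vals.mean()) < 1e-10
                assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_missing_features_imputed_to_zero_and_masked(self, small_extraction):
        extractions, reference = small_extraction
        raw, mask, _ = assemble_features(extractions, reference)
        X = standardize_features(raw)
        assert mask.to_numpy().any()  # some pairs lack PACE events etc.
        assert (X.to_numpy()[mask.to_numpy()] == 0.0).all()
        assert np.isfinite(X.to_numpy()).all()

    def test_feature_registry_counts(self):
        assert len([f for f in FEATURE_NAMES if f.startswith("cert_")]) == 18
        assert len([f for f in FEATURE_NAMES if f.startswith("clear_")]) == 25
        assert len([f for f in FEATURE_NAMES if f.startswith("pace_")]) == 5


def _separable_data(n=80, p=6, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 1, (n, p))
    X[:, 0] += 4 * y
    return X, y


class TestTraining:
    def test_singleton_grid_returns_that_configuration(self):
        X, y = _separable_data()
        spec = ModelSpec("l1_logreg", grid={"C": [0.1]}, seed=0)
        _, best, results = tune_and_train(spec, X, y, folds=3)
        assert best["C"] == 0.1
        assert len(results) == 1

    @pytest.mark.parametrize(
        "family", ["l1_logreg", "random_forest", "svm_rbf", "neural_net"]
    )
    def test_separable_fixture_reaches_high_cv_auroc(self, family):
        X, y = _separable_data()
        spec = ModelSpec(family, seed=0)
        _, _, results = tune_and_train(spec, X, y, folds=3)
        assert results["mean_cv_auroc"].iloc[0] >= 0.95

    def test_same_seed_selects_same_hyperparameters(self):
        X, y = _separable_data(seed=4)
        spec = ModelSpec("l1_logreg", grid={"C": [0.01, 1.0, 100.0]}, seed=7)
        _, b1, _ = tune_and_train(spec, X, y, folds=3)
        _, b2, _ = tune_and_train(spec, X, y, folds=3)
        assert b1 == b2

    def test_paper_defaults_are_model_spec_defaults(self):
        assert ModelSpec("random_forest").params == {
            "n_estimators": 250, "max_depth": 25, "min_samples_leaf": 10,
        }
        assert ModelSpec("l1_logreg").params == {"penalty": "l1", "C": 1}
        assert ModelSpec("svm_rbf").params == {"C": 10, "gamma": 0.01}
        assert ModelSpec("neural_net").params == {"n_hidden_layers": 3}


class TestPredictSignal:
    class _Stub:
        def __init__(self, probs):
            self.probs = np.asarray(probs)

        def predict_proba(self, X):
            return np.c_[1 - self.probs, self.probs]

    def test_threshold_is_strictly_greater(self):
        pred, scores = predict_signal(self._Stub([0.5, 0.5001, 0.4]), np.zeros((3, 1)))
        assert list(pred) == [False, True, False]

    def test_svm_probabilities_monotone_in_decision_score(self):
        X, y = _separable_data(seed=2)
        model = make_model(ModelSpec("svm_rbf", seed=0))
        model.fit(X, y)
        scores = model.predict_proba(X)[:, 1]
        margins = model.decision_function(X)
        order = np.argsort(margins)
        assert (np.diff(scores[order]) >= -1e-12).all()
        assert scores.min() >= 0.0 and scores.max() <= 1.0


class TestEvaluate:
    def test_perfect_classifier(self):
        y = np.array([0, 1, 0, 1])
        m = evaluate(y, y.astype(bool), y.astype(float))
        assert (
            m.sensitivity, m.specificity, m.ppv, m.npv, m.f1, m.auroc
        ) == (1, 1, 1, 1, 1, 1)

    def test_confusion_arithmetic(self):
        y_true = np.array([1] * 5 + [0] * 5)
        y_pred = np.array([True] * 3 + [False] * 2 + [True] * 1 + [False] * 4)
        m = evaluate(y_true, y_pred)
        assert (m.tp, m.fp, m.tn, m.fn) == (3, 1, 4, 2)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)
        assert m.ppv == pytest.approx(0.75)
        assert m.npv == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / (0.75 + 0.6))

    def test_metric_identities_hold_for_random_confusions(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, 50)
            p = rng.random(50) < 0.5
            if len(np.unique(y)) < 2:
                continue
            m = evaluate(y, p)
            assert m.tp + m.fn == y.sum()
            assert m.tn + m.fp == (1 - y).sum()
            if not math.isnan(m.sensitivity):
                assert m.sensitivity == m.tp / (m.tp + m.fn)

    def test_random_scores_auroc_near_half(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 5000)
        m = evaluate(y, np.zeros(10000, bool), rng.random(10000))
        assert m.auroc == pytest.approx(0.5, abs=0.02)


class TestRepeatedCV:
    def test_smoke_run_counts_models(self):
        X, y = _separable_data(n=40)
        out = repeated_cv_evaluation(
            X, y, [ModelSpec("l1_logreg", seed=0)], X, y, reps=1, folds=2, seed=0
        )
        assert len(out["l1_logreg"]["table"]) == 2

    def test_metric_bounds(self):
        X, y = _separable_data(n=40, seed=3)
        out = repeated_cv_evaluation(
            X, y, [ModelSpec("random_forest", seed=0)], X, y, reps=2, folds=2, seed=0
        )
        t = out["random_forest"]["table"]
        metrics = t[["sensitivity", "specificity", "ppv", "npv", "f1", "auroc"]]
        # degenerate all-negative folds leave PPV/F1 undefined (NaN)
        assert ((metrics >= 0) & (metrics <= 1) | metrics.isna()).all().all()
        summary = out["random_forest"]["summary"]
        assert (summary.loc["std"].dropna() >= 0).all()


class TestCompareAuroc:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0.8, 0.01, 50)
        res = compare_auroc({"a": base, "b": base.copy()})
        assert res["anova_p"] > 0.9
        assert res["tukey"]["mean_diff"].abs().max() < 1e-12

    def test_mean_differences_antisymmetric(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(0.7 + i * 0.02, 0.02, 30) for i, k in
                  enumerate("abc")}
        tk = compare_auroc(groups)["tukey"].set_index(["model_i", "model_j"])
        for (i, j), row in tk.iterrows():
            assert row["mean_diff"] == pytest.approx(
                -tk.loc[(j, i), "mean_diff"]
            )
            assert row["ci_lower"] == pytest.approx(-tk.loc[(j, i), "ci_upper"])

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(2)
        res = compare_auroc(
            {"hi": rng.normal(0.8, 0.01, 100), "lo": rng.normal(0.7, 0.01, 100)}
        )
        assert res["anova_p"] < 0.01
        assert (res["tukey"]["p_adj"] < 0.01).all()


class TestFeatureImportance:
    def test_rf_importances_sum_to_one(self):
        X, y = _separable_data()
        models = []
        for seed in range(3):
            m = make_model(ModelSpec("random_forest", seed=seed))
            m.fit(X, y)
            models.append(m)
        imp = feature_importance({"random_forest": models}, [f"f{i}" for i in range(6)])
        assert imp["gini_importance"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_signal_feature_outranks_noise(self):
        hits = 0
        for seed in range(10):
            X, y = _separable_data(seed=seed)
            rf = make_model(ModelSpec("random_forest", seed=seed))
            rf.fit(X, y)
            lr = make_model(ModelSpec("l1_logreg", seed=seed))
            lr.fit(X, y)
            imp = feature_importance(
                {"random_forest": [rf], "l1_logreg": [lr]},
                [f"f{i}" for i in range(6)],
            )
            if imp.loc["f0", "gini_rank"] == 1 and imp.loc["f0", "l1_rank"] == 1:
                hits += 1
        assert hits >= 9

    def test_huge_l1_regularization_zeroes_coefficients(self):
        X, y = _separable_data()
        m = make_model(ModelSpec("l1_logreg", params={"C": 1e-6}))
        m.fit(X, y)
        imp = feature_importance({"l1_logreg": [m]}, [f"f{i}" for i in range(6)])
        assert (imp["l1_magnitude"] == 0).all()


class TestComparatorEvaluation:
    def test_ccp3_positives_subset_of_ccp2(self, small_extraction):
        extractions, reference = small_extraction
        for ex in extractions.values():
            d = comparator_decisions(ex)
            if d["CCP3"]:
                assert d["CCP2"]

    def test_report_idempotent(self, small_extraction):
        extractions, reference = small_extraction
        r1 = comparator_evaluation(extractions, reference)
        r2 = comparator_evaluation(extractions, reference)
        pd.testing.assert_frame_equal(r1, r2)

    def test_all_negative_detector_metrics(self, small_extraction):
        extractions, reference = small_extraction
        report = comparator_evaluation(extractions, reference)
        # CERT400 cannot fire at this cohort size (needs > 400 paired patients)
        row = report.loc["CERT400"]
        assert row["sensitivity"] == 0.0
        assert row["specificity"] == 1.0
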