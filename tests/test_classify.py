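"""CFS selection, SVM/ANN classifiers and cross-validated evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from pdmotor import classify
from pdmotor.classify import (ANNClassifier, ConfusionMatrix, GAConfig,
                              SVMClassifier, cfs_select, cfs_select_exhaustive,
                              confusion_matrix, evaluate_cv, optimize_ann,
                              run_study, train_svm)


class _RuleClassifier(BaseEstimator, ClassifierMixin):
    """Deterministic rule y = f(X): oracle or constant predictors."""

    def __init__(self, rule):
        self.rule = rule

    def fit(self, X, y):
        return self

    def predict(self, X):
        return self.rule(np.asarray(X))


class TestMetrics:
    def test_closed_form_example(self):
        cm = ConfusionMatrix(TP=9, FP=2, FN=1, TN=8)
        assert cm.accuracy == pytest.approx(0.85)
        assert cm.sensitivity == pytest.approx(0.90)
        assert cm.specificity == pytest.approx(0.80)

    def test_counts_match_bruteforce(self, rng):
        for _ in range(20):
            y = rng.random(40) > 0.5
            p = rng.random(40) > 0.5
            cm = confusion_matrix(y, p)
            tp = sum(1 for a, b in zip(y, p) if a and b)
            tn = sum(1 for a, b in zip(y, p) if not a and not b)
            fp = sum(1 for a, b in zip(y, p) if not a and b)
            fn = sum(1 for a, b in zip(y, p) if a and not b)
            assert (cm.TP, cm.TN, cm.FP, cm.FN) == (tp, tn, fp, fn)
            assert cm.n == 40

    def test_always_positive_classifier(self, rng):
        """On a 56.3%-positive cohort an always-positive rule scores
        sensitivity 100, specificity 0, accuracy ~ prevalence."""
        n_pos, n_neg = 18, 14  # 56.25% positive, 32 instances
        X = pd.DataFrame({"f": rng.normal(size=n_pos + n_neg)})
        y = np.array([True] * n_pos + [False] * n_neg)
        rep = evaluate_cv(X, y, _RuleClassifier(lambda X: np.ones(len(X), bool)),
                          seed=0, spec="always-positive")
        assert rep.sensitivity == pytest.approx(100.0)
        assert rep.specificity == pytest.approx(0.0)
        assert rep.accuracy == pytest.approx(100 * n_pos / (n_pos + n_neg), abs=2.5)

    def test_perfect_oracle(self, rng):
        X = pd.DataFrame({"f": np.r_[rng.normal(2, 0.1, 20), rng.normal(-2, 0.1, 20)]})
        y = X["f"].to_numpy() > 0
        rep = evaluate_cv(X, y, _RuleClassifier(lambda X: X[:, 0] > 0), seed=0)
        assert (rep.accuracy, rep.sensitivity, rep.specificity) == (100.0, 100.0, 100.0)

    def test_instance_order_invariance(self, rng):
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = (X["a"] + rng.normal(0, 0.5, n)) > 0
        r1 = evaluate_cv(X, y, SVMClassifier("linear"), seed=3)
        perm = rng.permutation(n)
        r2 = evaluate_cv(X.iloc[perm].reset_index(drop=True), y[perm],
                         SVMClassifier("linear"), seed=3)
        assert r1.accuracy == pytest.approx(r2.accuracy)
        assert r1.sensitivity == pytest.approx(r2.sensitivity)
        assert r1.specificity == pytest.approx(r2.specificity)


class TestCFS:
    def test_single_informative_feature_selected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            y = rng.integers(0, 2, n).astype(bool)
            X = pd.DataFrame({"inf": y + rng.normal(0, 0.5, n),
                              **{f"noise{i}": rng.normal(size=n) for i in range(4)}})
            hits += cfs_select(X, y) == ["inf"]
        assert hits >= 19

    def test_redundant_copy_not_selected_twice(self, rng):
        n = 200
        y = rng.integers(0, 2, n).astype(bool)
        base = y + rng.normal(0, 0.5, n)
        X = pd.DataFrame({"a": base, "b": base.copy(),
                          "n1": rng.normal(size=n), "n2": rng.normal(size=n)})
        sel = cfs_select(X, y)
        assert sum(c in ("a", "b") for c in sel) == 1

    @pytest.mark.parametrize("p", [4, 6, 8])
    def test_best_first_matches_exhaustive(self, p):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 80
            y = rng.integers(0, 2, n).astype(bool)
            X = pd.DataFrame(
                {f"f{i}": y * rng.uniform(0, 1.2) + rng.normal(0, 1, n)
                 for i in range(p)})
            assert cfs_select(X, y) == cfs_select_exhaustive(X, y)

    def test_constant_feature_never_selected(self, rng):
        n = 100
        y = rng.integers(0, 2, n).astype(bool)
        X = pd.DataFrame({"c": np.ones(n), "inf": y + rng.normal(0, 0.4, n)})
        assert "c" not in cfs_select(X, y)


class TestSVM:
    def test_separable_blobs_perfect_training_accuracy(self, rng):
        X = pd.DataFrame(np.r_[rng.normal(3, 0.3, (25, 2)),
                               rng.normal(-3, 0.3, (25, 2))], columns=["a", "b"])
        y = np.r_[np.ones(25, bool), np.zeros(25, bool)]
        clf = train_svm(X, y, "linear")
        assert np.mean(clf.predict(X.to_numpy()) == y) == 1.0

    def test_xor_needs_nonlinear_kernel(self, rng):
        centers = [(2, 2, True), (-2, -2, True), (2, -2, False), (-2, 2, False)]
        pts, lab = [], []
        for cx, cy, l in centers:
            pts.append(rng.normal([cx, cy], 0.5, (40, 2)))
            lab += [l] * 40
        X = pd.DataFrame(np.vstack(pts), columns=["a", "b"])
        y = np.array(lab)
        lin = evaluate_cv(X, y, SVMClassifier("linear"), seed=1)
        rbf = evaluate_cv(X, y, SVMClassifier("gaussian"), seed=1)
        assert lin.accuracy <= 60.0
        assert rbf.accuracy >= 90.0

    def test_duplicating_instances_keeps_decision_function(self, rng):
        # separable case: duplicated instances leave the max-margin optimum
        X = np.r_[rng.normal(3, 0.3, (20, 2)), rng.normal(-3, 0.3, (20, 2))]
        y = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        probe = rng.normal(0, 3, (100, 2))
        c1 = SVMClassifier("linear").fit(X, y)
        c2 = SVMClassifier("linear").fit(np.r_[X, X], np.r_[y, y])
        assert np.array_equal(c1.predict(probe), c2.predict(probe))

    def test_single_class_fold_rejected(self):
        with pytest.raises(ValueError):
            SVMClassifier("linear").fit(np.zeros((5, 2)), np.ones(5, bool))

    def test_unknown_kernel(self):
        with pytest.raises(ValueError):
            SVMClassifier("sigmoid").fit(np.eye(4), np.array([0, 1, 0, 1], bool))


def _blob_table(rng, n=30):
    X = pd.DataFrame(np.r_[rng.normal(2, 0.4, (n, 2)),
                           rng.normal(-2, 0.4, (n, 2))], columns=["a", "b"])
    return X, np.r_[np.ones(n, bool), np.zeros(n, bool)]


class TestGAOptimizedANN:
    def test_converges_on_separable_blobs(self, rng):
        X, y = _blob_table(rng)
        cfg = GAConfig(population=8, generations=10, seed=1, n_permutations=2)
        result = optimize_ann(X, y, cfg)
        assert result.fitness >= 0.99
        assert len(result.history) == cfg.generations + 1

    def test_best_so_far_fitness_is_monotone(self, rng):
        X, y = _blob_table(rng)
        cfg = GAConfig(population=6, generations=6, seed=2, n_permutations=2)
        result = optimize_ann(X, y, cfg)
        assert all(b >= a for a, b in zip(result.history, result.history[1:]))
        assert result.fitness == result.history[-1]

    def test_same_seed_reproduces_topology_and_trace(self, rng):
        X, y = _blob_table(rng)
        cfg = GAConfig(population=6, generations=5, seed=7, n_permutations=2)
        r1 = optimize_ann(X, y, cfg)
        r2 = optimize_ann(X, y, cfg)
        assert r1.topology == r2.topology
        assert r1.history == r2.history

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(hidden_range=(5, 2)).validate()


@pytest.fixture(scope="module")
def cohort():
    from pdmotor import synth
    feats, _ = synth.generate_cohort(synth.case_config("A", seed=3))
    return feats


class TestStudyGrid:
    def test_report_has_all_models_and_subcases(self, cohort):
        cfg = GAConfig(population=6, generations=3, seed=0, n_permutations=2)
        rep = run_study(cohort, "A", "gait", seed=0, ga_config=cfg)
        assert len(rep) == 10  # 2 subcases x (4 SVMs + ANN)
        assert set(rep["subcase"]) == {"A.1", "A.2"}
        assert {"accuracy", "sensitivity", "specificity"} <= set(rep.columns)

    def test_selection_does_not_collapse_accuracy(self, cohort):
        rep = run_study(cohort, "A", "gait", seed=0, models=("gaussian",))
        a1 = float(rep[rep.subcase == "A.1"]["accuracy"].str.split("±").str[0].iloc[0])
        a2 = float(rep[rep.subcase == "A.2"]["accuracy"].str.split("±").str[0].iloc[0])
        assert a2 >= a1 - 5.0

    def test_label_permutation_gives_chance_level(self, cohort, rng):
        shuffled = cohort.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        rep = run_study(shuffled, "A", "gait", seed=0,
                        models=("linear", "gaussian"), subcases=(1,))
        accs = rep["accuracy"].str.split("±").str[0].astype(float)
        assert ((accs - 50.0).abs() <= 15.0).all()

    def test_missing_columns_named(self, cohort):
        broken = cohort.drop(columns=["STDl"])
        with pytest.raises(ValueError, match="STDl"):
            run_study(broken, "A", "gait", subcases=(1,), models=("linear",))

    def test_tapping_subcases(self, cohort):
        rep = run_study(cohort, "B", "tapping", seed=0, models=("gaussian",))
        assert list(rep["subcase"]) == ["B.1", "B.2", "B.3"]
        assert list(rep["n_features"]) == [8, 8, 16]
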