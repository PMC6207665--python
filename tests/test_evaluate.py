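"""LOO evaluation, dichotomies, ROC, confusion metrics, model comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fibrostage.evaluate import (
    DICHOTOMIES,
    Dichotomy,
    auroc,
    bootstrap_auroc_samples,
    compare_models,
    confusion_metrics,
    dichotomize,
    evaluation_report,
    loo_cv,
    loo_scores,
    roc_points,
    score_for,
)
from fibrostage.models import ClassifierSpec, ScoreMatrix


def auroc_pair_oracle(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestDichotomies:
    def test_the_four_standard_cutpoints(self):
        assert [d.name for d in DICHOTOMIES] == [
            "F0 vs F1-4", "F0-1 vs F2-4", "F0-2 vs F3-4", "F0-3 vs F4"]

    def test_dichotomize_at_advanced_fibrosis(self):
        labels = np.array([0, 1, 2, 3, 4])
        assert list(dichotomize(labels, Dichotomy(3))) == [0, 0, 0, 1, 1]

    def test_score_is_complement_of_f0_probability(self):
        row = np.array([[0.4, 0.3, 0.1, 0.1, 0.1]])
        s = score_for(ScoreMatrix(row), Dichotomy(1))
        assert s[0] == pytest.approx(0.6)

    def test_invalid_cutpoint_rejected(self):
        with pytest.raises(ValueError):
            Dichotomy(0)
        with pytest.raises(ValueError):
            Dichotomy(5)

    def test_labels_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dichotomize(np.array([0, 5]), Dichotomy(1))


class TestAUROC:
    def test_perfect_separation_is_one(self):
        assert auroc(np.array([1, 2, 3, 10, 11]),
                     np.array([0, 0, 0, 1, 1])) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auroc(np.ones(10), np.array([0, 1] * 5)) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(20), 1)  # coarse grid -> many ties
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        assert auroc(scores, labels) == pytest.approx(
            auroc_pair_oracle(scores, labels), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(16)
        labels = rng.integers(0, 2, 16)
        labels[:2] = [0, 1]
        a = auroc(scores, labels)
        b = auroc(np.exp(3 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_negated_scores_flip_the_area(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=14)  # continuous -> tie-free
        labels = rng.integers(0, 2, 14)
        labels[:2] = [0, 1]
        assert auroc(-scores, labels) == pytest.approx(
            1.0 - auroc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc(np.arange(4.0), np.zeros(4, dtype=int))

    def test_roc_curve_endpoints_and_area(self):
        rng = np.random.default_rng(4)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        r = roc_points(scores, labels)
        assert r.fpr[0] == 0 and r.tpr[0] == 0
        assert r.fpr[-1] == 1 and r.tpr[-1] == 1
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)
        assert np.trapezoid(r.tpr, r.fpr) == pytest.approx(r.auroc)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3, 4] * 4)
        cm = confusion_metrics(y, y, Dichotomy(2))
        assert cm.as_dict() == {"sensitivity": 1.0, "specificity": 1.0,
                                "ppv": 1.0, "npv": 1.0}

    def test_constructed_confusion_table(self):
        # TP=8, FN=2, FP=1, TN=9 at cutpoint 3
        pred = np.array([4] * 8 + [0] * 2 + [4] * 1 + [0] * 9)
        true = np.array([4] * 10 + [0] * 10)
        cm = confusion_metrics(pred, true, Dichotomy(3))
        assert cm.sensitivity == pytest.approx(0.8)
        assert cm.specificity == pytest.approx(0.9)
        assert cm.ppv == pytest.approx(8 / 9)
        assert cm.npv == pytest.approx(9 / 11)

    def test_no_positive_predictions_flags_ppv(self):
        pred = np.zeros(10, dtype=int)
        true = np.array([0] * 5 + [4] * 5)
        cm = confusion_metrics(pred, true, Dichotomy(1))
        assert cm.ppv == 0.0
        assert "ppv" in cm.undefined


class TestLOO:
    def test_one_fit_and_row_per_sample(self):
        calls = []

        def fit_score(Xtr, ytr, xte):
            calls.append(len(Xtr))
            return np.full(5, 0.2)

        X = np.zeros((100, 3))
        y = np.tile(np.arange(5), 20)
        pooled = loo_cv(X, y, fit_score)
        assert pooled.shape == (100, 5)
        assert len(calls) == 100
        assert all(c == 99 for c in calls)

    def test_separable_features_perfect_pooled_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(4 * k, 0.2, (4, 2)) for k in range(5)])
        y = np.repeat(np.arange(5), 4)
        sm = loo_scores(X, y, ClassifierSpec(family="mlr", seed=0))
        assert (sm.argmax_labels(np.arange(5)) == y).mean() == 1.0

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 3))
        y = np.tile(np.arange(5), 3)
        spec = ClassifierSpec(family="rf", n_trees=10, seed=5)
        a = loo_scores(X, y, spec).scores
        b = loo_scores(X, y, spec).scores
        assert np.array_equal(a, b)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            loo_cv(np.zeros((1, 2)), np.zeros(1), lambda *a: np.zeros(5))


def wmw_exact_oracle(x, y):
    """Exact two-sided WMW p-value by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for comb in itertools.combinations(range(n + m), n):
        u = ranks[list(comb)].sum() - n * (n + 1) / 2
        us.append(u)
    us = np.array(us)
    mu = n * m / 2
    p = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
    return p


class TestCompareModels:
    def test_five_models_ten_pairs_bonferroni(self):
        rng = np.random.default_rng(0)
        samples = {f"m{i}": rng.random(20) for i in range(5)}
        r = compare_models(samples)
        assert len(r.pairwise_p) == 10
        assert r.critical_p == pytest.approx(0.005)

    def test_identical_samples_show_no_evidence(self):
        r = compare_models({"a": np.full(10, 0.9), "b": np.full(10, 0.9)})
        assert r.kw_p == pytest.approx(1.0)
        assert not any(r.significant.values())

    def test_clearly_different_samples_flagged(self):
        rng = np.random.default_rng(1)
        r = compare_models({"good": 0.95 + 0.01 * rng.random(30),
                            "bad": 0.55 + 0.01 * rng.random(30)})
        assert r.kw_p < 0.05
        assert all(r.significant.values())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_wmw_matches_exact_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(0.5, 1.0, size=6)
        p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert p_scipy == pytest.approx(wmw_exact_oracle(x, y), abs=1e-10)

    def test_kw_equals_squared_wmw_z_for_two_groups(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = rng.normal(0.3, 1.0, size=10)
        h = stats.kruskal(x, y).statistic
        u = stats.mannwhitneyu(x, y).statistic
        n, m = len(x), len(y)
        z = (u - n * m / 2) / np.sqrt(n * m * (n + m + 1) / 12)
        assert h == pytest.approx(z**2, rel=1e-10)

    def test_unequal_sample_sizes_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            compare_models({"a": np.ones(5), "b": np.ones(6)})


@pytest.fixture(scope="module")
def tiny_report():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(3 * k, 0.5, (4, 21)) for k in range(5)])
    feats = np.hstack([X, rng.normal(size=(20, 109))])
    y = np.repeat(np.arange(5), 4)
    specs = {"rf": ClassifierSpec(family="rf", n_trees=15, seed=0),
             "mlr": ClassifierSpec(family="mlr", seed=0)}
    return evaluation_report(feats, y, specs, feature_sets=("morph",),
                             n_boot=25, seed=0)


class TestReport:
    def test_row_per_model_and_dichotomy(self, tiny_report):
        table, comps = tiny_report
        assert len(table) == 2 * 4
        assert set(table["dichotomy"]) == {d.name for d in DICHOTOMIES}
        assert len(comps) == 4

    def test_metrics_in_unit_interval(self, tiny_report):
        table, _ = tiny_report
        for col in ("auroc", "sensitivity", "specificity", "ppv", "npv"):
            assert table[col].between(0, 1).all()

    def test_bootstrap_samples_are_seeded(self):
        rng = np.random.default_rng(5)
        scores = ScoreMatrix(rng.dirichlet(np.ones(5), size=20))
        labels = np.repeat(np.arange(5), 4)
        a = bootstrap_auroc_samples(scores, labels, Dichotomy(2),
                                    n_boot=10, seed=3)
        b = bootstrap_auroc_samples(scores, labels, Dichotomy(2),
                                    n_boot=10, seed=3)
        assert np.array_equal(a, b)
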