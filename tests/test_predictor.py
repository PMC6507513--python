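import warnings

import numpy as np
import pytest
import statsmodels.api as sm

import vnsreact as v
from vnsreact.predictor import (
    PerformanceReport,
    _fit_logistic,
    _nested_loo,
    binomial_vs_chance,
)

from .conftest import make_separable_features
from .oracles import binomial_upper_tail_direct


class TestLogisticEngine:
    def test_loglik_matches_statsmodels(self):
        """The Newton-IRLS fits agree with statsmodels Logit (oracle)."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            X = rng.normal(size=(40, 3))
            y = (X[:, 0] + 0.5 * rng.normal(size=40) > 0).astype(float)
            design = np.column_stack([np.ones(40), X])
            beta, ll, conv = _fit_logistic(design, y)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = sm.Logit(y, design).fit(disp=0)
            assert conv
            assert ll == pytest.approx(ref.llf, abs=1e-6)
            assert beta == pytest.approx(ref.params, abs=1e-4)


class TestStepwiseSelection:
    def test_planted_feature_selected(self):
        rng = np.random.default_rng(1)
        n = 40
        y = np.repeat([1, 0], n // 2)
        X = rng.normal(size=(n, 30))
        X[:, 17] = y * 4 + rng.normal(0, 0.5, n)  # dominant signal
        sel = v.stepwise_logistic_select(X, y)
        assert 17 in sel

    def test_duplicate_informative_columns_tie_break_low_index(self):
        rng = np.random.default_rng(2)
        n = 30
        y = np.repeat([1, 0], n // 2)
        signal = y * 3 + rng.normal(0, 0.8, n)
        X = np.column_stack([rng.normal(size=n), signal, signal,
                             rng.normal(size=n)])
        sel = v.stepwise_logistic_select(X, y)
        assert 1 in sel and 2 not in sel

    def test_null_features_rarely_build_large_models(self):
        rng = np.random.default_rng(3)
        sizes = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(30):
                X = rng.normal(size=(30, 40))
                y = rng.integers(0, 2, 30).astype(float)
                if min(y.sum(), 30 - y.sum()) < 2:
                    continue
                sizes.append(len(v.stepwise_logistic_select(X, y)))
        # with p_enter = 0.05 over 40 candidates some false entries are
        # expected, but the model stays far from the n/10 cap on average
        assert 0 < np.mean(sizes) < 3.0

    def test_constant_columns_dropped_with_warning(self):
        X, y = make_separable_features()
        X = np.column_stack([X, np.full(len(y), 2.5)])
        with pytest.warns(UserWarning, match="constant"):
            sel = v.stepwise_logistic_select(X, y)
        assert X.shape[1] - 1 not in sel

    def test_separable_data_uses_penalized_fallback(self):
        X, y = make_separable_features(n_per_class=8)
        sel = v.stepwise_logistic_select(X, y)  # must not blow up
        assert 0 in sel


class TestLooSelectionFrequency:
    def test_dominant_feature_always_retained(self):
        rng = np.random.default_rng(4)
        n = 20
        y = np.repeat([1, 0], n // 2)
        X = rng.normal(size=(n, 10))
        X[:, 3] = y * 5 + rng.normal(0, 0.4, n)
        freq = v.loo_selection_frequency(X, y)
        assert freq[3] == n
        assert freq.attrs["n_iterations"] == n

    def test_minimal_cohort_runs_three_iterations(self):
        X = np.array([[0.1], [2.0], [-1.0], [1.5]])
        y = np.array([0, 1, 0, 1])
        freq = v.loo_selection_frequency(X, y)
        assert freq.attrs["n_iterations"] == 4

    def test_bit_identical_across_runs(self, small_cohort):
        rpw, labels, _ = small_cohort
        fm = v.build_grouped_features(rpw)
        f1 = v.loo_selection_frequency(fm, labels)
        f2 = v.loo_selection_frequency(fm, labels)
        assert f1.equals(f2)


class TestTopFeaturesAndSweep:
    def test_threshold_examples(self):
        import pandas as pd
        freq = pd.Series([60, 40, 35, 2])
        freq.attrs["n_iterations"] = 60
        assert v.top_features(freq, 35) == [0, 1, 2]
        assert v.top_features(freq, 1) == [0, 1, 2, 3]
        sparse = pd.Series([40, 35, 2])
        sparse.attrs["n_iterations"] = 60
        with pytest.warns(UserWarning, match="no features"):
            assert v.top_features(sparse, 60) == []
        with pytest.raises(ValueError):
            v.top_features(freq, 0)

    def test_monotone_in_threshold(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        freq = pd.Series(rng.integers(0, 20, 50))
        freq.attrs["n_iterations"] = 20
        prev = set(v.top_features(freq, 1))
        for t in range(2, 21):
            cur = set(v.top_features(freq, t)) if (freq >= t).any() else set()
            assert cur <= prev
            prev = cur

    def test_sweep_deterministic_and_monotone(self, small_cohort):
        rpw, labels, _ = small_cohort
        fm = v.build_grouped_features(rpw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = v.threshold_sweep(fm, labels)
            s2 = v.threshold_sweep(fm, labels)
        assert s1.equals(s2)
        assert (np.diff(s1["n_features"]) <= 0).all()

    def test_nested_mode_ignores_held_out_label(self):
        """Leakage guard: flipping a subject's label cannot change the
        nested-fold prediction for that subject."""
        rng = np.random.default_rng(6)
        n = 14
        y = np.repeat([1, 0], n // 2).astype(float)
        X = rng.normal(size=(n, 6))
        X[:, 0] += y * 2.5
        spec = v.ClassifierSpec("LR")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, preds = _nested_loo(X, y, 5, spec, None, return_preds=True)
            y_flip = y.copy()
            y_flip[3] = 1 - y_flip[3]
            _, preds_flip = _nested_loo(X, y_flip, 5, spec, None,
                                        return_preds=True)
        assert preds[3] == preds_flip[3]


class TestLooClassify:
    def test_reconstructed_confusion_counts_give_published_metrics(self):
        rep = PerformanceReport(tp=31, fp=4, tn=21, fn=4)
        assert rep.n == 60
        assert rep.accuracy == pytest.approx(86.7, abs=0.05)
        assert rep.sensitivity == pytest.approx(88.6, abs=0.05)
        assert rep.specificity == pytest.approx(84.0, abs=0.05)

    def test_separable_cohort_is_perfect(self):
        X, y = make_separable_features()
        rep = v.loo_classify(X, y, selected=[0])
        assert rep.accuracy == 100.0

    def test_empty_selection_rejected(self):
        X, y = make_separable_features()
        with pytest.raises(ValueError, match="empty"):
            v.loo_classify(X, y, selected=[])

    def test_degenerate_fold_rejected(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([1, 0, 0])
        with pytest.raises(ValueError, match="class"):
            v.loo_classify(X, y)

    @pytest.mark.parametrize("kind", ["LR", "SVM_linear", "LDA"])
    def test_all_classifier_families_run(self, kind):
        X, y = make_separable_features(n_per_class=6)
        rep = v.loo_classify(X, y, spec=v.ClassifierSpec(kind))
        assert rep.accuracy >= 90.0


class TestBinomialVsChance:
    def test_at_the_mean(self):
        assert binomial_vs_chance(30, 60, 0.5) > 0.5

    def test_matches_direct_tail_sum(self):
        for k, n, c in [(45, 60, 0.5), (12, 22, 0.545), (52, 60, 0.583)]:
            assert binomial_vs_chance(k, n, c) == pytest.approx(
                binomial_upper_tail_direct(k, n, c), rel=1e-10)

    def test_strong_result_is_significant(self):
        assert binomial_vs_chance(45, 60, 0.5) < 1e-3

    def test_perfect_closed_form(self):
        assert binomial_vs_chance(60, 60, 0.5) == pytest.approx(2.0**-60)
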