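import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvcohort.range_eval import (
    QuartileRange,
    classification_metrics,
    f1_from_rates,
    gluco_classify,
    group_quartiles,
    multiclass_auc,
    quartiles,
    rank_bin,
    rank_counts,
    rank_eval,
    regression_metrics,
    roc_auc,
)
from oracles import auc_pairs_direct

# pooled cross-validated confusion matrix of the reference
# extra-trees glucose-regulation classifier (rows = true BD/GD/ND)
CONFUSION = np.array([[4347, 225, 1716], [387, 2291, 1396], [801, 365, 10460]])


class TestQuartiles:
    def test_even_n_median_of_halves(self):
        assert quartiles(range(1, 9)) == (2.5, 4.5, 6.5)

    def test_odd_n_excludes_median_from_halves(self):
        assert quartiles([1, 2, 3, 4, 5]) == (1.5, 3, 4.5)

    def test_constant_values(self):
        assert quartiles([7.0] * 6) == (7.0, 7.0, 7.0)

    def test_order_preserved_under_monotone_transform(self, rng):
        # n = 23 makes all three quartiles data points (odd halves), so
        # they commute with any strictly monotone transform
        vals = rng.normal(50, 10, 23)
        q = quartiles(vals)
        qt = quartiles(np.exp(vals / 20))
        assert qt == tuple(np.exp(np.array(q) / 20))

    def test_brackets_median(self, rng):
        for _ in range(30):
            vals = rng.normal(size=rng.integers(4, 60))
            q1, q2, q3 = quartiles(vals)
            assert q1 <= q2 <= q3
            assert q2 == pytest.approx(float(np.median(vals)))


class TestGroupQuartiles:
    def test_per_cell_quartiles_and_mean(self, rng):
        ages = np.r_[np.full(10, 35.0), np.full(10, 65.0)]
        df = pd.DataFrame({
            "age": ages,
            "gender": ["M"] * 20,
            "A_SDNN": np.r_[np.arange(1.0, 11.0), np.arange(21.0, 31.0)],
        })
        ranges = group_quartiles(df, "A_SDNN")
        assert [(r.age_group, r.gender) for r in ranges] == [
            ("30-40", "M"), ("60-70", "M")]
        assert ranges[0].q2 == pytest.approx(5.5)
        assert ranges[0].mean == pytest.approx(5.5)

    def test_undersized_cells_omitted(self):
        df = pd.DataFrame({"age": [25, 25, 25], "gender": ["M"] * 3,
                           "A_SDNN": [1.0, 2.0, 3.0]})
        assert group_quartiles(df, "A_SDNN") == []

    def test_median_decreases_with_age_on_age_trended_data(self, rng):
        rows = []
        for gi, age_mid in enumerate([25, 35, 45, 55, 65, 75]):
            for _ in range(50):
                rows.append({
                    "age": age_mid + rng.uniform(-4, 4),
                    "gender": "M",
                    "A_SDNN": 60.62 - 0.49 * age_mid + rng.normal(0, 2),
                })
        ranges = group_quartiles(pd.DataFrame(rows), "A_SDNN")
        medians = [r.q2 for r in ranges]
        assert all(a > b for a, b in zip(medians, medians[1:]))


class TestRankEval:
    def test_partial_overlap(self):
        c = rank_counts({1, 2}, measured_bin=1)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 0, 2)

    def test_exhaustive_prediction(self):
        c = rank_counts({0, 1, 2, 3}, measured_bin=2)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 3, 0, 0)
        assert c.ppv == pytest.approx(0.25)

    def test_empty_prediction(self):
        c = rank_counts(set(), measured_bin=0)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 1, 3)

    def test_counts_always_sum_to_four(self):
        import itertools

        for r in range(5):
            for pred in itertools.combinations(range(4), r):
                for m in range(4):
                    c = rank_counts(set(pred), m)
                    assert c.tp + c.fp + c.fn + c.tn == 4
                    assert c.tp == (1 if m in pred else 0)

    def test_aggregation_is_additive(self):
        a = rank_counts({0}, 0) + rank_counts({1, 2}, 3)
        assert (a.tp, a.fp, a.fn, a.tn) == (1, 2, 1, 4)

    def test_quartile_range_to_bins(self):
        ref = QuartileRange(10, 20, 30, n=8)
        assert rank_bin(5, ref) == 0
        assert rank_bin(10, ref) == 0   # right-closed bins
        assert rank_bin(25, ref) == 2
        assert rank_bin(31, ref) == 3
        pred = QuartileRange(12, 18, 25, n=8)
        c = rank_eval(pred, measured_value=15, reference=ref)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 0, 2)


class TestF1:
    @pytest.mark.parametrize(
        "tpr,ppv,expected", [(1.0, 0.25, 0.4), (1.0, 1.0, 1.0),
                             (0.5, 1.0, 2 / 3), (0.0, 0.0, 0.0)]
    )
    def test_harmonic_mean(self, tpr, ppv, expected):
        assert f1_from_rates(tpr, ppv) == pytest.approx(expected)

    def test_range_check(self):
        with pytest.raises(ValueError):
            f1_from_rates(1.2, 0.5)


class TestClassificationMetrics:
    def test_reference_confusion_matrix_exact(self):
        m = classification_metrics(CONFUSION)
        assert m["accuracy"] == 17098 / 21988
        assert m["recall"][0] == 4347 / 6288
        assert m["recall"][1] == 2291 / 4074
        assert m["recall"][2] == 10460 / 11626
        assert m["macro_recall"] == pytest.approx(
            (4347 / 6288 + 2291 / 4074 + 10460 / 11626) / 3)
        assert round(m["accuracy"], 4) == 0.7776
        assert round(m["macro_recall"], 4) == 0.7178

    def test_perfect_and_uniform(self):
        assert classification_metrics(np.diag([5, 5, 5]))["accuracy"] == 1.0
        m = classification_metrics(np.ones((2, 2), dtype=int))
        assert m["accuracy"] == 0.5
        assert m["recall"].tolist() == [0.5, 0.5]

    def test_zero_row_warns(self):
        with pytest.warns(UserWarning):
            m = classification_metrics(np.array([[3, 0], [0, 0]]))
        assert m["accuracy"] == 1.0


class TestROCAUC:
    def test_reference_cases(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_matches_all_pairs_concordance(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 31))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.normal(size=n), 1)
            assert roc_auc(s, y) == pytest.approx(
                auc_pairs_direct(s.tolist(), y.tolist()), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestRegressionMetrics:
    def test_fixture(self):
        m = regression_metrics([0, 0], [3, 4])
        assert m.mse == pytest.approx(12.5)
        assert m.rmse == pytest.approx(np.sqrt(12.5))
        assert m.mae == pytest.approx(3.5)

    def test_identities(self, rng):
        y = rng.normal(size=40)
        yhat = y + rng.normal(0, 0.3, 40)
        m = regression_metrics(y, yhat)
        assert m.rmse == pytest.approx(np.sqrt(m.mse))
        assert m.mae <= m.rmse + 1e-12

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([1, 2], [1])


class TestGlucoClassify:
    @staticmethod
    def _features(rng, n, means):
        labels = rng.choice(["ND", "GD", "BD"], n, p=[0.5, 0.25, 0.25])
        base = np.array([means[l] for l in labels])
        X = pd.DataFrame({
            "A_SDNN": base + rng.normal(0, 1, n),
            "A_rMSSD": base * 0.7 + rng.normal(0, 1, n),
            "C_SDNN": base * 1.2 + rng.normal(0, 1, n),
            "C_rMSSD": base * 0.8 + rng.normal(0, 1, n),
        })
        return X, labels

    def test_separable_classes_high_f1(self, rng):
        X, y = self._features(rng, 300, {"ND": 50.0, "GD": 35.0, "BD": 20.0})
        res = gluco_classify(X, y, folds=10, random_state=0)
        assert res["macro_f1"] > 0.9
        assert res["confusion"].sum() == 300
        assert res["auc"] > 0.95

    def test_shuffled_labels_near_chance(self, rng):
        X, y = self._features(rng, 300, {"ND": 40.0, "GD": 40.0, "BD": 40.0})
        y = rng.permutation(y)
        res = gluco_classify(X, y, folds=10, random_state=0)
        assert abs(res["macro_f1"] - 1 / 3) <= 0.1

    def test_single_class_rejected(self):
        X = pd.DataFrame({"A_SDNN": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            gluco_classify(X, ["ND", "ND", "ND"])

    def test_small_class_reduces_folds(self, rng):
        X, y = self._features(rng, 40, {"ND": 50.0, "GD": 30.0, "BD": 10.0})
        with pytest.warns(UserWarning):
            res = gluco_classify(X, y, folds=30, random_state=0)
        assert res["folds"] < 30


@given(st.sets(st.integers(0, 3)), st.integers(0, 3))
@settings(derandomize=True, deadline=None, max_examples=80)
def test_property_rank_counts_partition(pred, measured):
    c = rank_counts(pred, measured)
    assert c.tp + c.fp + c.fn + c.tn == 4
    assert min(c.tp, c.fp, c.fn, c.tn) >= 0
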