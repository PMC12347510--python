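import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import lenssig as ls
from lenssig.evaluate import condition_log2_ci
from lenssig.exceptions import MetricError

from _oracles import auc_all_pairs
from conftest import make_matrix


class TestAucScore:
    def test_worked_example(self):
        assert ls.auc_score([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.2]) == pytest.approx(0.75)

    def test_forced_extremes(self):
        assert ls.auc_score([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert ls.auc_score([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        scores = np.round(rng.normal(size=n), 1)  # coarse grid to force ties
        expected = auc_all_pairs(labels, scores)
        assert ls.auc_score(labels, scores) == pytest.approx(expected, abs=1e-12)

    def test_mann_whitney_identity(self):
        rng = np.random.default_rng(4)
        labels = np.array([0] * 12 + [1] * 8)
        scores = rng.normal(size=20)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert ls.auc_score(labels, scores) == pytest.approx(u / (12 * 8), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            ls.auc_score([1, 1, 1], [0.1, 0.2, 0.3])


class TestConfusionAndPr:
    def test_all_correct_five_plus_five(self):
        labels = [0] * 5 + [1] * 5
        scores = [0.1] * 5 + [0.9] * 5
        rep = ls.confusion_and_pr(labels, scores)
        assert rep.accuracy == 1.0
        assert rep.auc == 1.0
        np.testing.assert_array_equal(rep.confusion, [[5, 0], [0, 5]])

    def test_one_wh_misclassified(self):
        labels = np.array([0] * 5 + [1] * 5)
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.4] + [0.9, 0.8, 0.95, 0.85, 0.75])
        rep = ls.confusion_and_pr(labels, scores)
        np.testing.assert_array_equal(rep.confusion, [[4, 1], [0, 5]])
        assert rep.accuracy == pytest.approx(0.9)

    def test_degenerate_all_one_class_predicted(self):
        labels = np.array([0] * 5 + [1] * 5)
        scores = np.full(10, 0.9)
        rep = ls.confusion_and_pr(labels, scores)
        assert rep.confusion[:, 0].sum() == 0      # nothing predicted WH
        assert rep.accuracy == pytest.approx(0.5)

    def test_invariants_roc_ends_and_accuracy_identity(self):
        rng = np.random.default_rng(1)
        labels = np.array([0, 1] * 6)
        scores = rng.uniform(size=12)
        rep = ls.confusion_and_pr(labels, scores)
        np.testing.assert_allclose(rep.roc_points[0], [0, 0])
        np.testing.assert_allclose(rep.roc_points[-1], [1, 1])
        assert rep.confusion.sum() == 12
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / 12)
        assert rep.auc == pytest.approx(np.trapezoid(rep.roc_points[:, 1],
                                                     rep.roc_points[:, 0]))


class TestPerGeneRoc:
    def _holdout(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5, 1, size=(4, 10))
        vals[0] = np.array([2] * 5 + [9] * 5) + rng.normal(0, 0.1, 10)  # F high
        vals[3] = 7.0                                                   # constant
        return make_matrix(vals, ["WH"] * 5 + ["F"] * 5, unit="log2(TPM+1)")

    def test_separating_gene_scores_one(self):
        auc, direction = ls.per_gene_roc(self._holdout(), "g0")
        assert auc == 1.0 and direction == "F_high"

    def test_orientation_identity(self):
        m = self._holdout()
        flipped = make_matrix(-m.values.to_numpy(), list(m.condition),
                              unit=m.unit, genes=list(m.gene_ids))
        for g in ("g1", "g2"):
            a1, d1 = ls.per_gene_roc(m, g)
            a2, d2 = ls.per_gene_roc(flipped, g)
            assert a1 == pytest.approx(a2)           # orientation-corrected
            assert {d1, d2} <= {"F_high", "F_low"} and d1 != d2

    def test_constant_gene_flagged_flat(self):
        auc, direction = ls.per_gene_roc(self._holdout(), "g3")
        assert auc == 0.5 and direction == "flat"


class TestPooledLog2fc:
    def _matrix(self, f_vals, wh_vals):
        vals = np.array([list(wh_vals) + list(f_vals)])
        return make_matrix(vals, ["WH"] * len(wh_vals) + ["F"] * len(f_vals))

    def test_worked_ratio(self):
        m = self._matrix([8.0, 8.0], [2.0, 2.0])
        rec = ls.pooled_log2fc(m, "g0")
        assert rec["log2fc"] == pytest.approx(2.0)

    def test_identical_means_give_zero(self):
        m = self._matrix([3.0, 5.0], [5.0, 3.0])
        assert ls.pooled_log2fc(m, "g0")["log2fc"] == pytest.approx(0.0)

    def test_swapping_conditions_negates(self):
        rng = np.random.default_rng(7)
        vals = rng.gamma(2, 10, size=(1, 8))
        m = make_matrix(vals, ["WH"] * 4 + ["F"] * 4)
        m_sw = make_matrix(vals, ["F"] * 4 + ["WH"] * 4)
        a = ls.pooled_log2fc(m, "g0")["log2fc"]
        b = ls.pooled_log2fc(m_sw, "g0")["log2fc"]
        assert a == pytest.approx(-b)

    def test_zero_mean_offset_flagged(self):
        m = self._matrix([4.0, 4.0], [0.0, 0.0])
        rec = ls.pooled_log2fc(m, "g0", offset=1.0)
        assert rec["zero_mean_offset_applied"]
        assert rec["log2fc"] == pytest.approx(np.log2(5.0))

    def test_ci_covers_the_condition_mean(self):
        rng = np.random.default_rng(8)
        vals = rng.gamma(3, 20, size=(1, 18))
        m = make_matrix(vals, ["WH"] * 9 + ["F"] * 9)
        ci = condition_log2_ci(m, "g0")
        for _, row in ci.iterrows():
            assert row["ci_low"] <= row["mean_log2"] <= row["ci_high"]


class TestPcaProjection:
    def test_separated_classes_split_on_pc1(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(5, 0.5, size=(50, 12))
        vals[:20, 6:] += 4.0     # strong shared shift for F samples
        m = make_matrix(vals, ["WH"] * 6 + ["F"] * 6, unit="log2(TPM+1)")
        coords, var = ls.pca_projection(m)
        pc1 = coords["PC1"].to_numpy()
        wh, f = pc1[:6], pc1[6:]
        assert (wh.mean() - f.mean()) ** 2 > (wh.std() + f.std()) ** 2
        assert 0 < var.sum() <= 1.0

    def test_duplicated_samples_identical_coordinates(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(20, 5))
        vals = np.hstack([base, base[:, :1]])
        m = make_matrix(vals, ["WH", "WH", "F", "F", "F", "WH"],
                        unit="log2(TPM+1)")
        coords, _ = ls.pca_projection(m)
        np.testing.assert_allclose(coords.iloc[0][["PC1", "PC2"]].to_numpy(dtype=float),
                                   coords.iloc[5][["PC1", "PC2"]].to_numpy(dtype=float),
                                   atol=1e-9)
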