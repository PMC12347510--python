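import numpy as np
import pytest

import lenssig as ls
from lenssig.exceptions import ParameterError
from lenssig.importance import permutation_importance_auc
from sklearn.svm import SVC

from conftest import make_matrix


def _one_informative(seed=0, n_genes=40, n=12, gap=4.0):
    """Matrix where exactly one gene separates the classes."""
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    vals = rng.normal(5.0, 1.0, size=(n_genes, n))
    vals[0] = 5.0 + gap * y + rng.normal(0, 0.2, n)
    conds = ["WH" if c == 0 else "F" for c in y]
    return make_matrix(vals, conds, unit="log2(TPM+1)")


class TestLinearRanking:
    def test_single_separating_gene_ranks_first(self):
        m = _one_informative()
        ranking = ls.SvmPanel(m, ls.SvmParams(seed=0)).rank_linear_svm()
        assert ranking.index[0] == "g0"
        # cross-check with a univariate AUC oracle: g0 has the top AUC too
        aucs = {g: ls.auc_score(m.y, m.values.loc[g].to_numpy()) for g in m.gene_ids}
        assert max(aucs, key=lambda g: max(aucs[g], 1 - aucs[g])) == "g0"

    def test_duplicated_gene_ties_broken_by_id(self):
        m = _one_informative(n_genes=10)
        vals = m.values.copy()
        vals.loc["g0_copy"] = vals.loc["g0"]
        m2 = make_matrix(vals.to_numpy(), list(m.condition), unit=m.unit,
                         genes=list(vals.index))
        ranking = ls.SvmPanel(m2, ls.SvmParams(seed=0)).rank_linear_svm()
        w0 = ranking["g0"]
        w0c = ranking["g0_copy"]
        # identical columns share the relevance equally (up to solver tolerance)
        assert w0 == pytest.approx(w0c, rel=1e-4)
        # and the ranking is reproducible run to run
        again = ls.SvmPanel(m2, ls.SvmParams(seed=0)).rank_linear_svm()
        assert list(ranking.index) == list(again.index)

    def test_invariant_to_sample_order(self):
        m = _one_informative(seed=3)
        r1 = ls.SvmPanel(m, ls.SvmParams(seed=0)).rank_linear_svm()
        perm = list(np.random.default_rng(1).permutation(list(m.sample_ids)))
        r2 = ls.SvmPanel(m.subset_samples(perm), ls.SvmParams(seed=0)).rank_linear_svm()
        np.testing.assert_allclose(r1.to_numpy(), r2.loc[r1.index].to_numpy(),
                                   rtol=1e-4, atol=1e-6)
        assert r1.index[0] == r2.index[0]

    def test_single_class_rejected(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(5, 4)),
                        ["F"] * 4, unit="log2(TPM+1)")
        with pytest.raises(ParameterError):
            ls.SvmPanel(m)


class TestPermutationImportance:
    def test_null_gene_importance_near_zero(self):
        means = []
        for rep in range(8):
            m = _one_informative(seed=rep)
            sub = m.subset_genes(["g0", "g1"])
            scores = permutation_importance_auc(
                SVC(kernel="rbf", random_state=0), sub.X, sub.y, ["g0", "g1"],
                n_permutations=50, seed=rep,
            )
            means.append(dict((s.gene_id, s.mean_auc_drop) for s in scores)["g1"])
        assert abs(float(np.mean(means))) < 0.05

    def test_single_gene_model_importance_near_half(self):
        m = _one_informative(seed=1)
        sub = m.subset_genes(["g0"])
        scores = permutation_importance_auc(
            SVC(kernel="rbf", random_state=0), sub.X, sub.y, ["g0"],
            n_permutations=100, seed=1,
        )
        # destroying the only feature sends AUC to ~0.5: drop ~ baseline - 0.5
        assert scores[0].mean_auc_drop == pytest.approx(0.5, abs=0.1)

    def test_gene_outside_model_scores_exactly_zero(self):
        m = _one_informative(seed=2)
        sub = m.subset_genes(["g0", "g1"])
        scores = permutation_importance_auc(
            SVC(kernel="rbf", random_state=0), sub.X, sub.y, ["g0", "g1"],
            probe_genes=["g0", "g5"], n_permutations=20, seed=2,
        )
        by_id = {s.gene_id: s for s in scores}
        assert by_id["g5"].mean_auc_drop == 0.0
        assert by_id["g5"].sd_auc_drop == 0.0
        assert not by_id["g5"].retained

    def test_constant_gene_flagged(self):
        m = _one_informative(seed=4)
        vals = m.values.copy()
        vals.loc["g1"] = 7.7
        m2 = make_matrix(vals.to_numpy(), list(m.condition), unit=m.unit,
                         genes=list(vals.index))
        sub = m2.subset_genes(["g0", "g1"])
        scores = permutation_importance_auc(
            SVC(kernel="rbf", random_state=0), sub.X, sub.y, ["g0", "g1"],
            n_permutations=10, seed=0,
        )
        by_id = {s.gene_id: s for s in scores}
        assert by_id["g1"].mean_auc_drop == 0.0 and not by_id["g1"].retained


class TestCalibratedRbf:
    def test_separated_panel_classifies_holdout_perfectly(self):
        train = _one_informative(seed=5)
        holdout = _one_informative(seed=6)
        res = ls.fit_calibrated_rbf(train, ["g0"], ls.SvmParams(seed=5))
        probs = res.predict_proba(holdout)
        assert ls.auc_score(holdout.y, probs) == 1.0
        predicted = probs >= 0.5
        np.testing.assert_array_equal(predicted, holdout.y.astype(bool))

    def test_decision_sign_convention_and_monotonicity(self):
        train = _one_informative(seed=7)
        res = ls.fit_calibrated_rbf(train, ["g0"], ls.SvmParams(seed=7))
        dv = res.decision_value(train)
        prob_f = res.predict_proba(train)
        # fibrosis samples sit on the negative side
        assert (dv[train.y == 1] < 0).all()
        assert (dv[train.y == 0] > 0).all()
        # decision values and P(F) are inversely monotone: same sample ordering
        assert (np.argsort(dv) == np.argsort(-prob_f)).all()

    def test_permuted_labels_give_chance_auc(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            train = _one_informative(seed=seed)
            y_perm = rng.permutation(train.y)
            conds = ["F" if c else "WH" for c in y_perm]
            shuffled = make_matrix(train.values.to_numpy(), conds, unit=train.unit,
                                   genes=list(train.gene_ids))
            holdout = _one_informative(seed=seed + 100)
            fitted = ls.SvmPanel(shuffled, ls.SvmParams(seed=seed)).fit()
            aucs.append(ls.auc_score(holdout.y, fitted.predict_proba(holdout)))
        assert 0.35 <= float(np.mean(aucs)) <= 0.65
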