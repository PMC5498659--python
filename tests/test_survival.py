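import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lpcbps import (
    BPSMatrix,
    ClinicalTable,
    CoxModel,
    cluster_association,
    fit_cox_lasso,
    logrank_test,
    loocv_evaluate,
    pi_cutoff,
    prognostic_index,
    risk_groups,
    roc_auc,
    transfer_evaluate,
)


def _clinical(time, status, ids=None):
    ids = ids or [f"s{i}" for i in range(len(time))]
    return ClinicalTable(pd.DataFrame({"sample": ids, "time": time, "status": status}))


def _features(values, ids=None, names=None):
    values = np.atleast_2d(values)
    ids = ids or [f"s{i}" for i in range(values.shape[1])]
    names = names or [f"p{i}" for i in range(values.shape[0])]
    return BPSMatrix(values, names, ids)


class TestPrognosticIndex:
    def test_zero_coefficients_give_zero_index(self):
        model = CoxModel(beta=pd.Series([0.0, 0.0], index=["p0", "p1"]), penalty=1.0)
        pi = prognostic_index(model, _features(np.random.default_rng(0).uniform(size=(2, 5))))
        assert np.allclose(pi, 0.0)

    def test_unit_vector_selects_single_feature(self):
        X = np.array([[0.1, 0.4, 0.9], [5.0, 5.0, 5.0]])
        model = CoxModel(beta=pd.Series([1.0, 0.0], index=["p0", "p1"]), penalty=0.0)
        assert prognostic_index(model, _features(X)).to_numpy() == pytest.approx(X[0])

    def test_hand_arithmetic(self):
        model = CoxModel(beta=pd.Series([1.0, -2.0], index=["p0", "p1"]), penalty=0.0)
        X = np.array([[0.5], [0.25]])
        assert prognostic_index(model, _features(X)).to_numpy() == pytest.approx([0.0])

    def test_missing_feature_rejected(self):
        model = CoxModel(beta=pd.Series([1.0], index=["absent"]), penalty=0.0)
        with pytest.raises(ValueError, match="missing"):
            prognostic_index(model, _features(np.ones((1, 3))))


class TestPiCutoff:
    def test_single_event_puts_one_sample_high(self):
        cutoff = pi_cutoff(np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 0, 0, 1]))
        assert 3.0 < cutoff < 4.0
        assert (np.array([1.0, 2.0, 3.0, 4.0]) > cutoff).sum() == 1

    def test_half_events_give_median_split(self):
        pi = np.array([10.0, 20.0, 30.0, 40.0])
        cutoff = pi_cutoff(pi, np.array([1, 0, 1, 0]))
        assert (pi > cutoff).sum() == 2

    def test_tied_pi_collapses_to_one_group_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="lpcbps.survival"):
            cutoff = pi_cutoff(np.full(6, 2.0), np.array([1, 0, 0, 1, 0, 0]))
        assert (np.full(6, 2.0) > cutoff).sum() == 0
        assert any("equal" in r.message for r in caplog.records)

    def test_uniform_status_rejected(self):
        with pytest.raises(ValueError, match="events"):
            pi_cutoff(np.arange(4.0), np.ones(4))

    @given(
        n=st.integers(min_value=4, max_value=60),
        k=st.integers(min_value=1, max_value=59),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_high_risk_fraction_matches_event_fraction(self, n, k, seed):
        if k >= n:
            return
        rng = np.random.default_rng(seed)
        pi = rng.permutation(np.linspace(0, 1, n))  # distinct values
        status = np.zeros(n, dtype=int)
        status[rng.choice(n, size=k, replace=False)] = 1
        cutoff = pi_cutoff(pi, status)
        d = k / n
        assert abs((pi > cutoff).mean() - d) <= 1.0 / n + 1e-12


class TestLogrank:
    def test_identical_groups_not_significant(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 2)
        status = np.array([1, 0, 1, 1, 0] * 2)
        group = np.array(["a"] * 5 + ["b"] * 5)
        assert logrank_test(time, status, group) > 0.99

    def test_strongly_separated_groups_significant(self):
        rng = np.random.default_rng(10)
        t_low = rng.exponential(1.0, 100)
        t_high = rng.exponential(1.0 / 5.0, 100)  # hazard ratio 5
        time = np.concatenate([t_low, t_high])
        status = np.ones(200, dtype=int)
        group = np.array(["low"] * 100 + ["high"] * 100)
        assert logrank_test(time, status, group) < 0.01
        assert logrank_test(time, status, group, weighted=True) < 0.01

    def test_invariant_to_label_swap(self):
        rng = np.random.default_rng(11)
        time = rng.exponential(1.0, 60)
        status = rng.integers(0, 2, 60)
        group = np.array(["a"] * 30 + ["b"] * 30)
        swapped = np.where(group == "a", "b", "a")
        assert logrank_test(time, status, group) == pytest.approx(
            logrank_test(time, status, swapped)
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 non-empty groups"):
            logrank_test(np.ones(4), np.ones(4), np.array(["a"] * 4))


class TestRocAuc:
    def test_perfectly_ordered_scores_give_one(self):
        assert roc_auc(np.arange(10.0), np.array([0] * 5 + [1] * 5)) == 1.0

    def test_sign_reversal_mirrors_auc(self):
        rng = np.random.default_rng(12)
        pi = rng.normal(size=40)
        status = rng.integers(0, 2, 40)
        status[0], status[1] = 0, 1
        assert roc_auc(-pi, status) == pytest.approx(1.0 - roc_auc(pi, status))

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(13)
        pi = rng.normal(size=4000)
        status = rng.integers(0, 2, 4000)
        assert roc_auc(pi, status) == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(14)
        pi = rng.normal(size=50).round(1)  # ties likely
        status = rng.integers(0, 2, 50)
        status[:2] = [0, 1]
        pos = pi[status == 1]
        neg = pi[status == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(pi, status) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_auc(np.arange(4.0), np.ones(4))


class TestFitCoxLasso:
    def test_recovers_sign_of_risk_coefficient(self):
        rng = np.random.default_rng(15)
        x = rng.uniform(size=300)
        time = rng.exponential(np.exp(-2.0 * x))
        clin = _clinical(np.maximum(time, 1e-9), np.ones(300, dtype=int))
        model = fit_cox_lasso(_features(x[None, :]), clin, penalty_selection="fixed",
                              alpha=0.01)
        assert model.beta.iloc[0] > 0

    def test_infinite_penalty_zeroes_all_coefficients(self):
        rng = np.random.default_rng(16)
        X = rng.uniform(size=(5, 80))
        time = rng.exponential(1.0, 80)
        clin = _clinical(time, rng.integers(0, 2, 80))
        model = fit_cox_lasso(_features(X), clin, penalty_selection="fixed", alpha=1e6)
        assert model.selected == []
        assert np.allclose(model.beta, 0.0)

    def test_too_few_events_rejected(self):
        clin = _clinical(np.arange(1, 13, dtype=float), np.zeros(12, dtype=int))
        with pytest.raises(ValueError, match="events"):
            fit_cox_lasso(_features(np.random.default_rng(0).uniform(size=(2, 12))), clin)

    def test_non_finite_features_rejected(self):
        X = np.ones((2, 12))
        X[0, 0] = np.nan
        clin = _clinical(np.arange(1, 13, dtype=float),
                         np.array([1, 1] + [0] * 10))
        with pytest.raises(ValueError, match="finite"):
            fit_cox_lasso(_features(X), clin)


class TestLoocv:
    def _null_data(self, n=60, p=5, seed=17):
        rng = np.random.default_rng(seed)
        X = rng.uniform(size=(p, n))
        time = rng.exponential(1.0, n)
        status = rng.integers(0, 2, n)
        status[:4] = [1, 1, 0, 0]
        return _features(X), _clinical(time, status)

    def test_null_features_give_near_half_auc(self):
        feats, clin = self._null_data()
        res = loocv_evaluate(feats, clin, penalty_selection="fixed", alpha=0.05)
        assert res["auc"] == pytest.approx(0.5, abs=0.1)

    def test_per_sample_table_has_one_row_per_fold(self):
        feats, clin = self._null_data()
        res = loocv_evaluate(feats, clin, penalty_selection="fixed", alpha=0.05)
        assert res["n_folds"] == 60
        assert len(res["per_sample"]) == 60
        assert res["per_sample"]["pi"].notna().all()

    def test_small_cohorts_rejected(self):
        feats, clin = self._null_data(n=8)
        with pytest.raises(ValueError, match="at least 10"):
            loocv_evaluate(feats, clin)


class TestAffineEquivariance:
    def test_constant_feature_shifts_pi_uniformly(self):
        rng = np.random.default_rng(18)
        X = rng.uniform(size=(3, 50))
        time = rng.exponential(1.0, 50)
        status = rng.integers(0, 2, 50)
        status[:2] = [0, 1]
        beta = pd.Series([0.8, -0.3, 0.5], index=["p0", "p1", "p2"])
        model = CoxModel(beta=beta, penalty=0.1)
        pi = prognostic_index(model, _features(X)).to_numpy()

        X_aug = np.vstack([X, np.full(50, 2.0)])
        beta_aug = pd.Series([0.8, -0.3, 0.5, 1.7], index=["p0", "p1", "p2", "const"])
        model_aug = CoxModel(beta=beta_aug, penalty=0.1)
        pi_aug = prognostic_index(
            model_aug, _features(X_aug, names=["p0", "p1", "p2", "const"])
        ).to_numpy()

        assert np.allclose(pi_aug - pi, 1.7 * 2.0)
        assert roc_auc(pi, status) == pytest.approx(roc_auc(pi_aug, status))
        g = risk_groups(pi, pi_cutoff(pi, status))
        g_aug = risk_groups(pi_aug, pi_cutoff(pi_aug, status))
        assert np.array_equal(g, g_aug)
        assert logrank_test(time, status, g) == pytest.approx(
            logrank_test(time, status, g_aug)
        )


class TestTransfer:
    def test_cutoff_applies_unchanged_to_second_cohort(self):
        rng = np.random.default_rng(19)
        beta = pd.Series([1.0], index=["p0"])
        model = CoxModel(beta=beta, penalty=0.1)
        X_train = rng.uniform(size=(1, 80))
        time_tr = rng.exponential(np.exp(-2 * X_train[0]))
        status_tr = np.ones(80, dtype=int)
        status_tr[:20] = 0
        clin_tr = _clinical(np.maximum(time_tr, 1e-9), status_tr)
        pi_tr = prognostic_index(model, _features(X_train)).to_numpy()
        cutoff = pi_cutoff(pi_tr, clin_tr.status)

        X_test = rng.uniform(size=(1, 70))
        ids = [f"t{i}" for i in range(70)]
        time_te = rng.exponential(np.exp(-2 * X_test[0]))
        status_te = rng.integers(0, 2, 70)
        status_te[:2] = [0, 1]
        clin_te = _clinical(np.maximum(time_te, 1e-9), status_te, ids=ids)
        res = transfer_evaluate(model, cutoff, _features(X_test, ids=ids), clin_te)
        assert res["cutoff"] == cutoff
        assert 0.0 <= res["auc"] <= 1.0


class TestClusterAssociation:
    def test_factor_equal_to_clusters_is_highly_significant(self):
        rng = np.random.default_rng(20)
        labels = np.array([0] * 50 + [1] * 50)
        X = np.vstack([labels + rng.normal(0, 0.05, 100) for _ in range(4)])
        ids = [f"s{i}" for i in range(100)]
        factors = pd.DataFrame({"grp": np.where(labels == 0, "x", "y")}, index=ids)
        table = cluster_association(_features(X, ids=ids), factors)
        assert table.loc[table["factor"] == "grp", "p_value"].iloc[0] < 1e-6

    def test_independent_factor_gives_uniformish_p(self):
        ps = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.uniform(size=(3, 200))
            ids = [f"s{i}" for i in range(200)]
            factors = pd.DataFrame(
                {"f": rng.choice(["a", "b"], 200)}, index=ids
            )
            table = cluster_association(_features(X, ids=ids), factors)
            ps.append(table["p_value"].iloc[0])
        assert 0.2 <= np.median(ps) <= 0.8

    def test_single_cluster_reported_as_error_per_factor(self):
        rng = np.random.default_rng(21)
        X = rng.uniform(size=(3, 30))
        ids = [f"s{i}" for i in range(30)]
        factors = pd.DataFrame({"f": rng.choice(["a", "b"], 30)}, index=ids)
        table = cluster_association(_features(X, ids=ids), factors, n_clusters=1)
        assert table["method"].str.contains("error").all()
        assert table["p_value"].isna().all()
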