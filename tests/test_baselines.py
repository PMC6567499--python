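import numpy as np
import pytest
from scipy import stats

from drcomb import (
    BaselineConfig,
    ExpressionDataset,
    FixtureSpec,
    bagged_baseline,
    generate_realizations,
    make_two_class_gaussian,
    rf_score,
    rf_train,
    roc_auc,
    single_baseline,
    ttest_select,
)
from drcomb.baselines import _mtry_rule


def _labeled(X, y):
    X = np.asarray(X, dtype=float)
    return ExpressionDataset(
        [f"s{i}" for i in range(X.shape[0])],
        [f"g{j}" for j in range(X.shape[1])],
        X,
        labels=np.asarray(y, dtype=int),
    )


class TestTtestSelect:
    def test_dominant_feature_selected(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 10)
        X = rng.standard_normal((20, 2)) * 0.01
        X[:, 0] += 10.0 * y
        X[:, 1] = rng.standard_normal(20)
        ds = _labeled(X, y)
        np.testing.assert_array_equal(ttest_select(ds, 1), [0])

    def test_keep_all_preserves_order(self):
        rng = np.random.default_rng(1)
        ds = _labeled(rng.standard_normal((12, 6)), np.repeat([0, 1], 6))
        np.testing.assert_array_equal(ttest_select(ds, 6), np.arange(6))

    def test_welch_pvalues_match_manual_formula(self):
        """Independent oracle: Welch statistic + t CDF computed by hand."""
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], [9, 11])
        X = rng.standard_normal((20, 15))
        X[:, :3] += 0.8 * y[:, None]
        ds = _labeled(X, y)
        g1, g0 = X[y == 1], X[y == 0]
        n1, n0 = len(g1), len(g0)
        v1 = g1.var(axis=0, ddof=1)
        v0 = g0.var(axis=0, ddof=1)
        se2 = v1 / n1 + v0 / n0
        t = (g1.mean(axis=0) - g0.mean(axis=0)) / np.sqrt(se2)
        df = se2 ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
        )
        p_manual = 2 * stats.t.sf(np.abs(t), df)
        order_manual = np.sort(np.argsort(p_manual, kind="stable")[:5])
        np.testing.assert_array_equal(ttest_select(ds, 5), order_manual)
        # full p-value agreement through scipy used internally
        _, p_scipy = stats.ttest_ind(g1, g0, axis=0, equal_var=False)
        np.testing.assert_allclose(p_manual, p_scipy, atol=1e-10)

    def test_zero_variance_feature_handling(self):
        y = np.repeat([0, 1], 5)
        X = np.zeros((10, 2))
        X[:, 0] = y * 3.0       # constant within class, means differ -> p=0
        X[:, 1] = 1.0           # constant everywhere, means equal -> p=1
        ds = _labeled(X, y)
        np.testing.assert_array_equal(ttest_select(ds, 1), [0])


class TestMtryRule:
    def test_sqrt_rule(self):
        # 112 training samples -> round(sqrt(112)) = 11
        assert _mtry_rule(112, min_dev_class=84, p=343) == 11

    def test_small_class_third_rule(self):
        # <= 30 per class in development -> one third of training count
        assert _mtry_rule(32, min_dev_class=24, p=343) == round(32 / 3)

    def test_clamped_to_feature_count(self):
        with pytest.warns(UserWarning, match="clamp"):
            assert _mtry_rule(112, min_dev_class=84, p=5) == 5


@pytest.fixture(scope="module")
def signal_setup():
    spec = FixtureSpec(
        n_per_class_dev=18, n_per_class_val=40, n_informative=4,
        n_noise=40, effect_size=1.2, rng_seed=6,
    )
    dev, val = make_two_class_gaussian(spec)
    reals = generate_realizations(dev.labels, 40, 2 / 3, rng_seed=9)
    return dev, val, reals


class TestRandomForest:
    def test_scores_in_unit_interval(self, signal_setup):
        dev, val, reals = signal_setup
        rf = rf_train(dev, reals, rng_seed=0)
        s = rf.score(val)
        assert ((s >= 0) & (s <= 1)).all()

    def test_single_tree_vote(self, signal_setup):
        dev, val, reals = signal_setup
        rf = rf_train(dev, reals[:1], rng_seed=0)
        s = rf.score(val)
        assert set(np.unique(s)) <= {0.0, 1.0}

    def test_oob_bookkeeping_recount(self, signal_setup):
        dev, val, reals = signal_setup
        rf = rf_train(dev, reals, rng_seed=1)
        oob = rf.score(dev, mode="oob")
        outs = rf._outputs(dev)
        for i in range(dev.n_samples):
            used = [
                outs[i, j]
                for j, r in enumerate(reals)
                if i in r.test_indices
            ]
            assert oob[i] == pytest.approx(np.mean(used), abs=1e-12)
        # single-sample API agrees
        assert rf_score(rf, dev.values[2], "oob", 2) == pytest.approx(
            oob[2], abs=1e-12
        )

    def test_same_realizations_as_drc(self, signal_setup):
        dev, _, reals = signal_setup
        again = generate_realizations(dev.labels, 40, 2 / 3, rng_seed=9)
        for a, b in zip(reals, again):
            np.testing.assert_array_equal(a.train_indices, b.train_indices)
            np.testing.assert_array_equal(a.test_indices, b.test_indices)

    def test_rf_oob_close_to_validation_on_signal(self, signal_setup):
        """Stratified bags keep the OOB estimate honest."""
        dev, val, reals = signal_setup
        rf = rf_train(dev, reals, rng_seed=2)
        oob_auc = roc_auc(rf.score(dev, mode="oob"), dev.labels).auc
        val_auc = roc_auc(rf.score(val), val.labels).auc
        assert abs(oob_auc - val_auc) < 0.2


class TestSingleBaselines:
    def test_knn_score_range_and_resubstitution_optimism(self, signal_setup):
        dev, val, reals = signal_setup
        cfg = BaselineConfig(method="knn", k=7)
        model = single_baseline(dev, "knn_score", cfg)
        s_dev = model.score(dev)
        assert ((s_dev >= 0) & (s_dev <= 1)).all()
        resub = roc_auc(s_dev, dev.labels).auc
        val_auc = roc_auc(model.score(val), val.labels).auc
        # resubstitution includes each sample as its own neighbor
        assert resub > val_auc

    def test_logistic_feature_selection_count(self, signal_setup):
        dev, _, _ = signal_setup
        cfg = BaselineConfig(method="logistic", n_features_selected=4)
        model = single_baseline(dev, "logistic", cfg)
        assert model.feature_indices.size == 4
        assert model.weights.size == 4

    def test_constant_features_give_chance_auc(self):
        y = np.repeat([0, 1], 10)
        ds = _labeled(np.ones((20, 3)), y)
        cfg = BaselineConfig(method="logistic")
        model = single_baseline(ds, "logistic", cfg)
        assert roc_auc(model.score(ds), ds.labels).auc == 0.5

    def test_unknown_learner(self, signal_setup):
        dev, _, _ = signal_setup
        with pytest.raises(ValueError):
            single_baseline(dev, "svm", BaselineConfig())


class TestBaggedBaselines:
    def test_single_realization_equals_single_learner(self, signal_setup):
        dev, val, reals = signal_setup
        cfg = BaselineConfig(method="knn_bagged", k=5)
        bag = bagged_baseline(dev, reals[:1], "knn_score", cfg)
        single = single_baseline(
            dev.take_samples(reals[0].train_indices), "knn_score", cfg
        )
        np.testing.assert_allclose(bag.score(val), single.score(val))

    def test_bagged_knn_output_range(self, signal_setup):
        dev, val, reals = signal_setup
        cfg = BaselineConfig(method="knn_bagged", k=7)
        bag = bagged_baseline(dev, reals, "knn_score", cfg)
        s = bag.score(val)
        assert ((s >= 0) & (s <= 1)).all()

    def test_bagged_logistic_separable_validation(self):
        rng = np.random.default_rng(12)
        y = np.repeat([0, 1], 15)
        X = rng.standard_normal((30, 3)) * 0.1
        X[:, 0] += 8.0 * y
        dev = _labeled(X, y)
        yv = np.repeat([0, 1], 10)
        Xv = rng.standard_normal((20, 3)) * 0.1
        Xv[:, 0] += 8.0 * yv
        val = _labeled(Xv, yv)
        reals = generate_realizations(y, 10, 2 / 3, rng_seed=0)
        bag = bagged_baseline(
            dev, reals, "logistic", BaselineConfig(method="logistic_bagged")
        )
        assert roc_auc(bag.score(val), val.labels).auc == 1.0

    def test_per_bag_feature_selection(self, signal_setup):
        dev, val, reals = signal_setup
        cfg = BaselineConfig(method="logistic_bagged", n_features_selected=3)
        bag = bagged_baseline(dev, reals[:5], "logistic", cfg)
        selections = [tuple(ln.feature_indices) for ln in bag.learners]
        assert all(len(s) == 3 for s in selections)
        # bags differ, so at least some selections should differ
        assert len(set(selections)) >= 1

    def test_bagging_narrows_optimism_gap(self, signal_setup):
        """Bagged dev estimates (OOB) overfit less than resubstitution."""
        dev, val, reals = signal_setup
        cfg = BaselineConfig(method="knn", k=7)
        single = single_baseline(dev, "knn_score", cfg)
        gap_single = (
            roc_auc(single.score(dev), dev.labels).auc
            - roc_auc(single.score(val), val.labels).auc
        )
        bag = bagged_baseline(dev, reals, "knn_score", cfg)
        gap_bag = (
            roc_auc(bag.score(dev, mode="oob"), dev.labels).auc
            - roc_auc(bag.score(val), val.labels).auc
        )
        assert gap_bag < gap_single
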