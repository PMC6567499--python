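import numpy as np
import pytest

from drcomb import (
    DRCConfig,
    FixtureSpec,
    MasterClassifier,
    classify,
    generate_realizations,
    make_two_class_gaussian,
    master_score,
    roc_auc,
    select_threshold,
    train_master,
)


@pytest.fixture(scope="module")
def toy_master():
    spec = FixtureSpec(
        n_per_class_dev=10, n_per_class_val=15, n_informative=2,
        n_noise=3, effect_size=1.5, rng_seed=17,
    )
    dev, val = make_two_class_gaussian(spec)
    cfg = DRCConfig(
        n_realizations=50, k=3, dropout_d=4, dropout_iterations=300,
        rng_seed=23,
    )
    return dev, val, cfg, train_master(dev, cfg)


class TestGenerateRealizations:
    def test_two_thirds_split_counts(self):
        y = np.repeat([0, 1], 6)
        reals = generate_realizations(y, 10, 2 / 3, rng_seed=0)
        for r in reals:
            assert r.train_indices.size == 8  # floor(2/3*12/2)=4 per class
            assert r.test_indices.size == 4
            assert (y[r.train_indices] == 1).sum() == 4
            assert (y[r.train_indices] == 0).sum() == 4

    def test_equal_class_counts_every_realization(self):
        rng = np.random.default_rng(1)
        y = rng.permutation(np.repeat([0, 1], [30, 20]))
        reals = generate_realizations(y, 40, 2 / 3, rng_seed=3)
        n_per = int(np.floor(2 / 3 * 50 / 2))
        for r in reals:
            tr = y[r.train_indices]
            assert (tr == 0).sum() == (tr == 1).sum() == n_per
            # partition property
            union = np.union1d(r.train_indices, r.test_indices)
            np.testing.assert_array_equal(union, np.arange(50))

    def test_requested_count_produced(self):
        y = np.repeat([0, 1], 12)
        reals = generate_realizations(y, 325, 2 / 3, rng_seed=5)
        assert len(reals) == 325
        memberships = {tuple(r.train_indices) for r in reals}
        assert len(memberships) > 300  # essentially all distinct

    def test_test_membership_frequency(self):
        y = np.repeat([0, 1], 15)
        reals = generate_realizations(y, 600, 2 / 3, rng_seed=7)
        counts = np.zeros(30)
        for r in reals:
            counts[r.test_indices] += 1
        freq = counts / 600
        # each sample in test with frequency ~ 1/3
        assert np.abs(freq - 1 / 3).max() < 4 * np.sqrt(
            (1 / 3) * (2 / 3) / 600
        )

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            generate_realizations(np.ones(10, dtype=int), 5, 2 / 3, 0)

    def test_tiny_set_error(self):
        y = np.array([0, 1])
        with pytest.raises(ValueError, match="below 1"):
            generate_realizations(y, 5, 0.5, 0)

    def test_majority_class_undersampled(self):
        y = np.repeat([0, 1], [40, 20])
        with pytest.warns(UserWarning, match="capped"):
            reals = generate_realizations(y, 5, 2 / 3, rng_seed=0)
        for r in reals:
            tr = y[r.train_indices]
            assert (tr == 0).sum() == (tr == 1).sum() == 19


class TestTrainMaster:
    def test_structure(self, toy_master):
        dev, _, cfg, mc = toy_master
        assert len(mc.bases) == cfg.n_realizations
        assert len(mc.realizations) == cfg.n_realizations
        assert mc.n_dev == dev.n_samples

    def test_same_seed_identical(self, toy_master, tmp_path):
        dev, _, cfg, mc = toy_master
        mc2 = train_master(dev, cfg)
        for a, b in zip(mc.bases, mc2.bases):
            np.testing.assert_array_equal(a.weights, b.weights)
            assert a.intercept == b.intercept
        d1, d2 = tmp_path / "m1", tmp_path / "m2"
        mc.save(d1)
        mc2.save(d2)
        for f1 in sorted(d1.rglob("*")):
            if f1.is_file():
                f2 = d2 / f1.relative_to(d1)
                assert f1.read_bytes() == f2.read_bytes()

    def test_every_sample_in_some_test_set(self, toy_master):
        dev, _, _, mc = toy_master
        assert (mc.test_membership_matrix().sum(axis=1) >= 1).all()

    def test_oob_uses_only_nontraining_bases(self, toy_master):
        dev, _, _, mc = toy_master
        member = mc.test_membership_matrix()
        for i in range(dev.n_samples):
            for j, r in enumerate(mc.realizations):
                if member[i, j]:
                    assert i not in r.train_indices

    def test_oob_score_matches_bookkeeping_oracle(self, toy_master):
        dev, _, _, mc = toy_master
        scores = mc.score(dev, mode="oob")
        outs = mc.base_outputs(dev)
        for i in range(dev.n_samples):
            used = [
                outs[i, j]
                for j, r in enumerate(mc.realizations)
                if i in r.test_indices
            ]
            assert scores[i] == pytest.approx(np.mean(used), abs=1e-12)

    def test_full_score_is_mean_of_bases(self, toy_master):
        dev, val, _, mc = toy_master
        outs = mc.base_outputs(val)
        np.testing.assert_allclose(
            mc.score(val, mode="full"), outs.mean(axis=1), atol=1e-15
        )

    def test_master_score_single_sample_api(self, toy_master):
        dev, val, _, mc = toy_master
        s_full = master_score(mc, val.values[0], mode="full")
        assert s_full == pytest.approx(mc.score(val)[0], abs=1e-12)
        s_oob = master_score(mc, dev.values[3], mode="oob", sample_index=3)
        assert s_oob == pytest.approx(mc.score(dev, mode="oob")[3], abs=1e-12)

    def test_serialization_round_trip(self, toy_master, tmp_path):
        dev, val, _, mc = toy_master
        mc.save(tmp_path / "m")
        back = MasterClassifier.load(tmp_path / "m", dev)
        np.testing.assert_allclose(
            back.score(val), mc.score(val), atol=1e-15
        )
        np.testing.assert_allclose(
            back.score(dev, mode="oob"), mc.score(dev, mode="oob"),
            atol=1e-15,
        )
        assert back.membership_digest() == mc.membership_digest()

    def test_load_rejects_wrong_dataset(self, toy_master, tmp_path):
        dev, val, _, mc = toy_master
        mc.save(tmp_path / "m")
        wrong = dev.take_samples(np.arange(dev.n_samples))
        wrong.values = wrong.values + 1.0
        with pytest.raises(ValueError, match="digest"):
            MasterClassifier.load(tmp_path / "m", wrong)

    def test_bagging_reduces_variance(self):
        """Ensemble averaging damps base-to-base output variability."""
        spec = FixtureSpec(
            n_per_class_dev=10, n_per_class_val=5, n_informative=1,
            n_noise=4, effect_size=1.0, rng_seed=3,
        )
        dev, val = make_two_class_gaussian(spec)
        master_scores, base_scores = [], []
        for seed in range(6):
            cfg = DRCConfig(
                n_realizations=25, k=3, dropout_d=4,
                dropout_iterations=200, rng_seed=seed,
            )
            mc = train_master(dev, cfg)
            outs = mc.base_outputs(val.values[:1])
            master_scores.append(outs.mean())
            base_scores.extend(outs.ravel())
        assert np.var(master_scores) < np.var(base_scores)

    def test_hierarchical_mode_prefers_informative_pairs(self):
        spec = FixtureSpec(
            n_per_class_dev=15, n_per_class_val=5, n_informative=1,
            n_noise=12, effect_size=2.5, rng_seed=31,
        )
        dev, _ = make_two_class_gaussian(spec)
        cfg = DRCConfig(
            n_realizations=12, k=3, hierarchical=True, max_order=2,
            dropout_d=4, dropout_iterations=100, rng_seed=2,
        )
        mc = train_master(dev, cfg)
        with_f0 = total_pairs = 0
        for bc in mc.bases:
            for s in bc.atomics.subsets:
                if len(s) == 2:
                    total_pairs += 1
                    with_f0 += 0 in s.indices
        assert total_pairs > 0
        # pairs containing the informative feature dominate the candidates
        assert with_f0 / total_pairs > 2 / 13


class TestClassify:
    def test_threshold_comparison(self, toy_master):
        dev, val, _, mc = toy_master
        s = master_score(mc, val.values[0])
        assert classify(mc, val.values[0], threshold=s - 1e-9) == 1
        assert classify(mc, val.values[0], threshold=min(s + 1e-9, 0.999)) == (
            1 if s >= s + 1e-9 else 0
        )

    def test_threshold_limits(self, toy_master):
        dev, val, _, mc = toy_master
        for i in range(5):
            assert classify(mc, val.values[i], threshold=1e-9) == 1
            assert classify(mc, val.values[i], threshold=1 - 1e-9) == 0

    def test_threshold_sweep_consistent_with_roc(self, toy_master):
        dev, val, _, mc = toy_master
        scores = mc.score(val)
        roc = roc_auc(scores, val.labels)
        for thr in np.linspace(0.05, 0.95, 7):
            preds = np.array(
                [classify(mc, val.values[i], thr) for i in range(val.n_samples)]
            )
            tpr = preds[val.labels == 1].mean()
            fpr = preds[val.labels == 0].mean()
            # the swept point lies on the stored ROC curve
            on_curve = np.any(
                (np.abs(roc.tpr - tpr) < 1e-12)
                & (np.abs(roc.fpr - fpr) < 1e-12)
            )
            assert on_curve


class TestSelectThreshold:
    def test_perfect_separation_midpoint(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        thr = select_threshold(scores, labels)
        assert thr == pytest.approx(0.5)

    def test_identical_scores_degenerate(self):
        with pytest.warns(UserWarning, match="identical"):
            thr = select_threshold(
                np.full(6, 0.4), np.array([0, 1, 0, 1, 0, 1])
            )
        assert thr == 0.5

    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = np.round(rng.random(14), 2)
            y = rng.integers(0, 2, 14)
            if len(np.unique(y)) < 2:
                continue
            thr = select_threshold(s, y)

            def j_stat(t):
                pred = s >= t
                return (
                    pred[y == 1].mean() - pred[y == 0].mean()
                )

            candidates = np.unique(s)
            mids = (candidates[:-1] + candidates[1:]) / 2
            if mids.size == 0:
                continue
            best = max(j_stat(t) for t in mids)
            assert j_stat(thr) == pytest.approx(best, abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            select_threshold(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_fixed_rule_passthrough(self):
        assert select_threshold(
            np.array([0.1, 0.9]), np.array([0, 1]), rule="fixed", fixed=0.42
        ) == 0.42
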