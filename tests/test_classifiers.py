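import numpy as np
import pytest

from gaitstate import classifiers as clf
from gaitstate.features import FEATURE_NAMES, CopFeatureSeries, featurize
from gaitstate.io import STANDING, WALKING, StateSeries
from gaitstate.simulate import GaitProfile, simulate_trial


class TestTamFit:
    def test_ten_percent_point(self):
        model = clf.tam_fit(np.array([0.0, 50.0, 100.0]))
        assert model.grf_threshold == pytest.approx(10.0)

    def test_degenerate_range_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            model = clf.tam_fit(np.full(10, 42.0))
        assert model.grf_threshold == pytest.approx(42.0)

    def test_random_series_match_direct_formula(self, rng):
        x = rng.uniform(0, 800, 1000)
        model = clf.tam_fit([x[:500], x[500:]])
        assert model.grf_threshold == pytest.approx(
            x.min() + (x.max() - x.min()) * 10.0 / 100.0
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            clf.tam_fit(np.array([]))


class TestTamClassify:
    def test_both_feet_loaded_is_standing(self, make_recording):
        rec = make_recording(np.full((10, 8), 40.0))  # 160 N per foot
        out = clf.tam_classify(rec, clf.TamModel(grf_threshold=21.0))
        assert (out.states == STANDING).all()

    def test_unloaded_swing_foot_is_walking(self, make_recording):
        forces = np.full((10, 8), 40.0)
        forces[:, :4] = 0.0  # left foot in swing
        rec = make_recording(forces)
        out = clf.tam_classify(rec, clf.TamModel(grf_threshold=21.0))
        assert (out.states == WALKING).all()

    def test_simulated_trial_matches_direct_rule(self):
        trial = simulate_trial(GaitProfile.patient(), seed=9)
        model = clf.tam_fit(
            [trial.recording.foot_sum("left"), trial.recording.foot_sum("right")]
        )
        out = clf.tam_classify(trial.recording, model)
        # oracle: direct re-evaluation of the per-foot rule
        expected = np.where(
            (trial.recording.foot_sum("left") > model.grf_threshold)
            & (trial.recording.foot_sum("right") > model.grf_threshold),
            STANDING,
            WALKING,
        )
        np.testing.assert_array_equal(out.states, expected)

    def test_total_rule_uses_two_foot_sum(self, make_recording):
        forces = np.full((5, 8), 10.0)
        forces[:, :4] = 0.0  # left unloaded; total = 40 N
        rec = make_recording(forces)
        th = clf.TamModel(grf_threshold=21.0)
        assert (clf.tam_classify(rec, th, rule="total").states == STANDING).all()
        assert (clf.tam_classify(rec, th, rule="per_foot").states == WALKING).all()


class TestCopwThreshold:
    def test_disjoint_classes_split_at_midpoint(self):
        stand = np.array([1.0, 4.0, 9.0])
        walk = np.array([101.0, 150.0, 300.0])
        model = clf.copw_select_threshold(stand, walk)
        assert model.copw_threshold == pytest.approx(55.0)
        pred = clf.copw_classify(np.concatenate([stand, walk]), model, 100.0)
        np.testing.assert_array_equal(pred.states, [0, 0, 0, 1, 1, 1])

    def test_identical_distributions_warn_but_resolve(self, rng):
        x = rng.normal(100, 10, 400)
        with pytest.warns(UserWarning, match="identical"):
            model = clf.copw_select_threshold(x, x.copy())
        assert np.isfinite(model.copw_threshold)

    def test_overlapping_gaussians_match_exhaustive_oracle(self, rng):
        stand = rng.normal(50, 15, 3000).clip(0)
        walk = rng.normal(120, 30, 3000).clip(0)
        bw = 5.0
        model = clf.copw_select_threshold(stand, walk, bin_width=bw)
        # independent oracle: exhaustive scan over the same aligned bins for
        # the bin with the largest overlap density min(p_s, p_w)
        pooled = np.concatenate([stand, walk])
        lo = pooled.min()
        n_bins = int(np.ceil((pooled.max() - lo) / bw))
        best, best_score = None, -1.0
        for b in range(n_bins):
            e0, e1 = lo + b * bw, lo + (b + 1) * bw
            last = b == n_bins - 1
            p_s = np.mean((stand >= e0) & ((stand < e1) | (last & (stand == e1))))
            p_w = np.mean((walk >= e0) & ((walk < e1) | (last & (walk == e1))))
            if p_s > 0 and p_w > 0 and min(p_s, p_w) > best_score:
                best_score = min(p_s, p_w)
                best = 0.5 * (e0 + e1)
        assert model.copw_threshold == pytest.approx(best)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            clf.copw_select_threshold(np.array([]), np.array([1.0]))

    def test_tie_at_threshold_classifies_as_walking(self):
        model = clf.CopwModel(copw_threshold=276.0)
        pred = clf.copw_classify(np.array([275.9, 276.0, 276.1]), model, 100.0)
        np.testing.assert_array_equal(pred.states, [0, 1, 1])


def _features_from_matrix(X, fs=100.0):
    import pandas as pd

    return CopFeatureSeries(
        sampling_rate=fs,
        data=pd.DataFrame(X, columns=FEATURE_NAMES),
        window_size=25,
        inter_foot_distance=0.33,
    )


class TestAnn:
    @pytest.fixture()
    def separable(self, rng):
        # linearly separable synthetic cohort: class decided by cop_w column
        n = 600
        X = rng.normal(0, 1, size=(n, 10))
        y = (rng.random(n) < 0.5).astype(int)
        X[:, 9] = np.where(y == 1, rng.uniform(500, 900, n), rng.uniform(10, 80, n))
        return _features_from_matrix(X), StateSeries(100.0, y)

    def test_training_is_deterministic_given_seed(self, separable):
        feats, labels = separable
        m1 = clf.ann_fit(feats, labels, seed=3, epochs=50)
        m2 = clf.ann_fit(feats, labels, seed=3, epochs=50)
        np.testing.assert_array_equal(m1.w_in, m2.w_in)
        np.testing.assert_array_equal(m1.w_out, m2.w_out)
        m3 = clf.ann_fit(feats, labels, seed=4, epochs=50)
        assert not np.array_equal(m1.w_in, m3.w_in)

    def test_separable_data_reaches_high_training_accuracy(self, separable):
        feats, labels = separable
        model = clf.ann_fit(feats, labels, seed=0, epochs=400)
        pred = clf.ann_predict(feats, model)
        assert np.mean(pred.states == labels.states) >= 0.99

    def test_single_class_labels_raise(self, separable):
        feats, _ = separable
        ones = StateSeries(100.0, np.ones(len(feats), dtype=int))
        with pytest.raises(ValueError, match="single class"):
            clf.ann_fit(feats, ones, epochs=5)

    def test_constant_features_give_constant_prediction(self):
        X = np.full((50, 10), 7.0)
        y = StateSeries(100.0, np.r_[np.zeros(25, int), np.ones(25, int)])
        model = clf.ann_fit(_features_from_matrix(X), y, epochs=20)
        pred = clf.ann_predict(_features_from_matrix(X), model)
        assert len(np.unique(pred.states)) == 1

    def test_forward_pass_matches_hand_computed_sigmoid(self):
        # one hidden node, hand-set weights
        def sig(z):
            return 1.0 / (1.0 + np.exp(-z))

        model = clf.AnnModel(
            input_names=[f"x{i}" for i in range(2)],
            norm_maxima=np.array([2.0, 4.0]),
            w_in=np.array([[0.5], [-1.0]]),
            b_in=np.array([0.25]),
            w_out=np.array([2.0]),
            b_out=-0.5,
            seed=0,
            epochs=0,
            learning_rate=0.0,
        )
        x = np.array([[1.0, 2.0]])  # normalized -> [0.5, 0.5]
        h = sig(0.5 * 0.5 + (-1.0) * 0.5 + 0.25)
        expected = sig(2.0 * h - 0.5)
        assert clf.ann_forward(model, x)[0] == pytest.approx(expected, abs=1e-12)

    def test_network_shape_is_validated(self):
        with pytest.raises(ValueError):
            clf.AnnModel(
                input_names=["a"],
                norm_maxima=np.ones(1),
                w_in=np.ones((1, 3)),
                b_in=np.ones(2),  # wrong
                w_out=np.ones(3),
                b_out=0.0,
                seed=0,
                epochs=0,
                learning_rate=0.1,
            )


class TestGarson:
    def _random_model(self, rng, n_in=10, n_hidden=20):
        return clf.AnnModel(
            input_names=[f"x{i}" for i in range(n_in)],
            norm_maxima=np.ones(n_in),
            w_in=rng.normal(0, 1, (n_in, n_hidden)),
            b_in=rng.normal(0, 1, n_hidden),
            w_out=rng.normal(0, 1, n_hidden),
            b_out=0.0,
            seed=0,
            epochs=0,
            learning_rate=0.1,
        )

    def test_single_active_input_takes_all_importance(self):
        w_in = np.zeros((10, 20))
        w_in[0] = 1.3
        model = clf.AnnModel(
            input_names=[f"x{i}" for i in range(10)],
            norm_maxima=np.ones(10),
            w_in=w_in,
            b_in=np.zeros(20),
            w_out=np.ones(20),
            b_out=0.0,
            seed=0,
            epochs=0,
            learning_rate=0.1,
        )
        imp = clf.garson_importance(model).importance
        np.testing.assert_allclose(imp, [100.0] + [0.0] * 9, atol=1e-12)

    def test_importances_sum_to_hundred_and_are_nonnegative(self, rng):
        for _ in range(20):
            rep = clf.garson_importance(self._random_model(rng))
            assert rep.importance.sum() == pytest.approx(100.0, abs=1e-9)
            assert (rep.importance >= 0).all()

    def test_matches_literal_formula_oracle(self, rng):
        model = self._random_model(rng, n_in=4, n_hidden=6)
        got = clf.garson_importance(model).importance
        # independent literal evaluation
        q = np.zeros(4)
        for i in range(4):
            for j in range(6):
                denom = sum(abs(model.w_in[k, j]) for k in range(4))
                q[i] += abs(model.w_in[i, j]) / denom * abs(model.w_out[j])
        np.testing.assert_allclose(got, 100.0 * q / q.sum(), atol=1e-10)

    def test_all_zero_weights_raise(self):
        model = clf.AnnModel(
            input_names=["a", "b"],
            norm_maxima=np.ones(2),
            w_in=np.zeros((2, 3)),
            b_in=np.zeros(3),
            w_out=np.zeros(3),
            b_out=0.0,
            seed=0,
            epochs=0,
            learning_rate=0.1,
        )
        with pytest.raises(ValueError):
            clf.garson_importance(model)


class TestSplitTrials:
    def test_split_is_disjoint_and_seeded(self):
        trials = list(range(40))
        tr1, te1 = clf.split_trials(trials, n_train=30, seed=5)
        tr2, te2 = clf.split_trials(trials, n_train=30, seed=5)
        assert tr1 == tr2 and te1 == te2
        assert len(tr1) == 30 and len(te1) == 10
        assert not set(tr1) & set(te1)
        tr3, _ = clf.split_trials(trials, n_train=30, seed=6)
        assert tr3 != tr1

    def test_bad_sizes_raise(self):
        with pytest.raises(ValueError):
            clf.split_trials([1, 2, 3], n_train=3, seed=0)


class TestModelPersistence:
    def test_yaml_round_trip_all_kinds(self, tmp_path, rng):
        models = [
            clf.TamModel(grf_threshold=21.5),
            clf.CopwModel(copw_threshold=276.0),
            clf.ann_fit(
                _features_from_matrix(rng.normal(0, 1, (40, 10))),
                StateSeries(100.0, np.r_[np.zeros(20, int), np.ones(20, int)]),
                epochs=5,
            ),
        ]
        for i, model in enumerate(models):
            path = tmp_path / f"m{i}.yaml"
            clf.save_model(model, path)
            back = clf.load_model(path)
            if isinstance(model, clf.AnnModel):
                np.testing.assert_array_equal(back.w_in, model.w_in)
                np.testing.assert_array_equal(back.norm_maxima, model.norm_maxima)
                assert back.input_names == model.input_names
            else:
                assert back == model


def test_threshold_rules_are_reproducible_and_order_invariant(rng):
    """Pure threshold rules: bit-exact reproducibility and per-sample locality
    (permuting samples permutes outputs identically)."""
    cop_w = rng.uniform(0, 1000, 500)
    model = clf.CopwModel(copw_threshold=300.0)
    a = clf.copw_classify(cop_w, model, 100.0).states
    b = clf.copw_classify(cop_w, model, 100.0).states
    np.testing.assert_array_equal(a, b)
    perm = rng.permutation(500)
    c = clf.copw_classify(cop_w[perm], model, 100.0).states
    np.testing.assert_array_equal(c, a[perm])
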