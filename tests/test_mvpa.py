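"""Normalization, pairwise SVM training and cross-classification."""

import numpy as np
import pytest
from sklearn.svm import SVC

import crossdecode as cd
from crossdecode import mvpa, svm


def _pattern_set(X, conds, runs=None, period="cue", modality="face"):
    runs = runs if runs is not None else np.ones(len(conds), int)
    return cd.PatternSet(np.asarray(X, float), conds, runs, period, modality)


class TestNormalization:
    def test_train_voxels_centered(self):
        rng = np.random.default_rng(0)
        ps = _pattern_set(rng.normal(2.0, 3.0, size=(20, 7)),
                          np.tile([1, 2, 3, 4], 5))
        tr, te = cd.normalize_patterns(ps, ps)
        assert np.abs(tr.X.mean(axis=0)).max() < 1e-10
        assert np.allclose(tr.X.std(axis=0), 1.0)
        assert np.array_equal(tr.X, te.X)

    def test_constant_voxel_maps_to_zero(self):
        X = np.ones((8, 3))
        X[:, 1] = np.arange(8)
        ps = _pattern_set(X, np.tile([1, 2], 4))
        tr, _ = cd.normalize_patterns(ps, ps)
        assert np.all(tr.X[:, 0] == 0)
        assert np.all(tr.X[:, 2] == 0)
        assert np.isfinite(tr.X).all()

    def test_matches_independent_transform(self):
        """Oracle re-implementation, including a condition-mean shift."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(16, 5))
        conds = np.tile([1, 2, 3, 4], 4)
        X[conds == 2] += 5.0           # univariate condition difference
        Xt = rng.normal(size=(8, 5))
        tr, te = cd.normalize_patterns(
            _pattern_set(X, conds), _pattern_set(Xt, np.tile([1, 2, 3, 4], 2)))
        mu, sd = X.mean(0), X.std(0)
        assert np.allclose(tr.X, (X - mu) / sd)
        assert np.allclose(te.X, (Xt - mu) / sd)

    def test_no_leakage_guard(self):
        """Statistics must come from train only: recomputing them with the
        test set included must give a different transform."""
        rng = np.random.default_rng(2)
        X = rng.normal(0.0, 1.0, size=(12, 4))
        Xt = rng.normal(3.0, 2.0, size=(12, 4))    # shifted test set
        tr_ps = _pattern_set(X, np.tile([1, 2], 6))
        te_ps = _pattern_set(Xt, np.tile([1, 2], 6), period="stim")
        _, te = cd.normalize_patterns(tr_ps, te_ps)
        joint_mu = np.vstack([X, Xt]).mean(0)
        joint_sd = np.vstack([X, Xt]).std(0)
        leaky = (Xt - joint_mu) / joint_sd
        assert not np.allclose(te.X, leaky)
        assert np.allclose(te.X, (Xt - X.mean(0)) / X.std(0))

    def test_voxel_count_mismatch(self):
        a = _pattern_set(np.zeros((4, 3)), [1, 2, 1, 2])
        b = _pattern_set(np.zeros((4, 5)), [1, 2, 1, 2])
        with pytest.raises(ValueError, match="voxel counts"):
            cd.normalize_patterns(a, b)


class TestTrainPairwise:
    def test_bank_sizes(self):
        rng = np.random.default_rng(3)
        ps4 = _pattern_set(rng.normal(size=(16, 6)), np.tile([1, 2, 3, 4], 4))
        assert cd.train_pairwise(ps4).n_pairs == 6
        ps2 = _pattern_set(rng.normal(size=(8, 6)), np.tile([1, 2], 4))
        assert cd.train_pairwise(ps2).n_pairs == 1

    def test_separable_toy_matches_max_margin(self):
        """Class means at (-1,0) and (+1,0), no noise: the max-margin
        separator is the vertical axis; w points along x with margin 1."""
        X = np.array([[-1.0, 0.0], [-1.0, 0.5], [1.0, 0.0], [1.0, -0.5]])
        ps = _pattern_set(X, [1, 1, 2, 2])
        bank = cd.train_pairwise(ps, cost=1.0)
        w, b = bank.weights[0], bank.biases[0]
        assert w[0] > 0 and abs(w[1]) < 1e-6 and abs(b) < 1e-6
        # training accuracy 1.0
        res = cd.cross_classify("cue_face", bank,
                                _pattern_set(X, [1, 1, 2, 2], period="stim"))
        assert res.accuracy == 1.0

    def test_missing_or_degenerate_condition(self):
        ps = _pattern_set(np.zeros((3, 2)), [1, 2, 2])
        with pytest.raises(ValueError, match="fewer than 2"):
            cd.train_pairwise(ps)
        with pytest.raises(ValueError, match="cost"):
            cd.train_pairwise(_pattern_set(np.zeros((4, 2)), [1, 1, 2, 2]),
                              cost=0.0)

    def test_agrees_with_libsvm_reference(self):
        """Dual-route check: in-package SMO vs sklearn's libsvm on random
        pair problems — identical predictions, matching primal objective."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            n, p = int(rng.integers(6, 30)), int(rng.integers(2, 40))
            X = rng.normal(size=(n, p)) + rng.normal(size=(1, p))
            y = np.where(rng.random(n) < 0.5, -1.0, 1.0)
            if abs(y.sum()) == n:
                y[0] *= -1
            w, b = svm.svc_fit(X, y, 1.0, 1e-5)
            ref = SVC(kernel="linear", C=1.0, tol=1e-6).fit(X, (y > 0))
            wr, br = ref.coef_.ravel(), ref.intercept_[0]
            Xt = rng.normal(size=(30, p))
            assert np.array_equal(np.sign(Xt @ w + b) >= 0,
                                  np.sign(Xt @ wr + br) >= 0)
            def primal(wv, bv):
                return 0.5 * wv @ wv + np.maximum(
                    0.0, 1.0 - y * (X @ wv + bv)).sum()
            assert primal(w, b) <= primal(wr, br) + 1e-3


class TestCrossClassify:
    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(11)
        Xtr = rng.normal(size=(32, 10))
        ctr = np.tile([1, 2, 3, 4], 8)
        accs = []
        for rep in range(50):
            Xte = rng.normal(size=(40, 10))
            cte = rng.permutation(np.tile([1, 2, 3, 4], 10))
            res = cd.decode(_pattern_set(Xtr, ctr),
                            _pattern_set(Xte, cte, period="stim"), "cue_face")
            accs.append(res.accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.03

    def test_scene_labels_mapped_through_association(self):
        """Scene test samples are scored as their associated face id."""
        rng = np.random.default_rng(13)
        assoc = {1: 3, 2: 1, 3: 4, 4: 2}
        lm = cd.LabelMap(assoc)
        proto = rng.normal(size=(4, 12)) * 4
        ctr = np.tile([1, 2, 3, 4], 6)
        Xtr = proto[ctr - 1] + rng.normal(size=(24, 12)) * 0.1
        # test patterns carry the face pattern of the scene's associated face
        scenes = np.tile([1, 2, 3, 4], 3)
        faces = np.array([lm.scene_to_face[s] for s in scenes])
        Xte = proto[faces - 1] + rng.normal(size=(12, 12)) * 0.1
        res = cd.decode(_pattern_set(Xtr, ctr, np.repeat(np.arange(6), 4)),
                        _pattern_set(Xte, scenes, period="oneback_delay",
                                     modality="scene"),
                        "delay_scene", label_map=lm)
        assert res.accuracy == 1.0
        with pytest.raises(ValueError, match="label map"):
            cd.decode(_pattern_set(Xtr, ctr),
                      _pattern_set(Xte, scenes, period="oneback_delay",
                                   modality="scene"), "delay_scene")

    def test_mean_is_mean_of_pair_accuracies(self):
        rng = np.random.default_rng(17)
        res = cd.decode(
            _pattern_set(rng.normal(size=(16, 8)), np.tile([1, 2, 3, 4], 4)),
            _pattern_set(rng.normal(size=(16, 8)), np.tile([1, 2, 3, 4], 4),
                         period="stim"), "cue_face")
        assert res.accuracy == pytest.approx(np.mean(res.pair_accuracies))
        assert np.all((res.pair_accuracies >= 0)
                      & (res.pair_accuracies <= 1))

    def test_label_permutation_symmetry(self):
        """Relabeling conditions by a permutation (and remapping the
        association accordingly) leaves accuracies unchanged."""
        rng = np.random.default_rng(19)
        proto = rng.normal(size=(4, 10)) * 2
        ctr = np.tile([1, 2, 3, 4], 5)
        Xtr = proto[ctr - 1] + rng.normal(size=(20, 10)) * 0.5
        cte = np.tile([1, 2, 3, 4], 3)
        Xte = proto[cte - 1] + rng.normal(size=(12, 10)) * 0.5
        lm = cd.LabelMap({1: 1, 2: 2, 3: 3, 4: 4})
        base = cd.decode(_pattern_set(Xtr, ctr),
                         _pattern_set(Xte, cte, period="stim"),
                         "cue_face", label_map=lm).accuracy
        perm = {1: 2, 2: 4, 3: 1, 4: 3}
        ctr_p = np.array([perm[c] for c in ctr])
        cte_p = np.array([perm[c] for c in cte])
        permuted = cd.decode(_pattern_set(Xtr, ctr_p),
                             _pattern_set(Xte, cte_p, period="stim"),
                             "cue_face", label_map=lm.permuted(perm)).accuracy
        assert base == pytest.approx(permuted)

    def test_chance_under_null_simulations(self):
        """Information amplitude 0: mean accuracy over 100 seeded
        simulations lies in [0.47, 0.53]."""
        rng = np.random.default_rng(23)
        accs = []
        for rep in range(100):
            Xtr = rng.normal(size=(16, 9))
            Xte = rng.normal(size=(8, 9))
            res = cd.decode(
                _pattern_set(Xtr, np.tile([1, 2, 3, 4], 4),
                             np.repeat([1, 2, 3, 4], 4)),
                _pattern_set(Xte, np.tile([1, 2, 3, 4], 2), period="stim"),
                "cue_face")
            accs.append(res.accuracy)
        assert 0.47 <= np.mean(accs) <= 0.53

    def test_double_dissociation_construction(self, informative_cohort,
                                              identity_label_map):
        """Delay-period ROI carrying associated-scene patterns decodes
        scenes but not faces; cue-period face ROI decodes faces."""
        from conftest import subjects_for
        fitted, truth, sim = informative_cohort
        lm = identity_label_map
        ppa_scene = np.mean([cd.mvpa.decode(s.train, s.test, "delay_scene",
                                            label_map=lm).accuracy
                             for s in subjects_for(fitted, truth, "PPA",
                                                   "delay_scene", lm)])
        ppa_face = np.mean([cd.mvpa.decode(s.train, s.test, "delay_face",
                                           label_map=lm).accuracy
                            for s in subjects_for(fitted, truth, "PPA",
                                                  "delay_face", lm)])
        ffa_cue = np.mean([cd.mvpa.decode(s.train, s.test, "cue_face",
                                          label_map=lm).accuracy
                           for s in subjects_for(fitted, truth, "FFA",
                                                 "cue_face", lm)])
        assert ppa_scene > 0.9
        assert abs(ppa_face - 0.5) < 0.15
        assert ffa_cue > 0.9

    def test_empty_test_set_raises(self):
        rng = np.random.default_rng(29)
        bank = cd.train_pairwise(_pattern_set(rng.normal(size=(8, 4)),
                                              np.tile([1, 2], 4)))
        empty = cd.PatternSet(np.empty((0, 4)), [], [], "stim", "face")
        with pytest.raises(ValueError, match="empty"):
            cd.cross_classify("cue_face", bank, empty)
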