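import numpy as np
import pytest

from rhizopore import classify as cl


class TestStructureLabels:
    def test_disjoint_masks_verbatim(self):
        shape = (8, 8, 8)
        pore = np.zeros(shape, bool)
        bio = np.zeros(shape, bool)
        root = np.zeros(shape, bool)
        pore[0] = True
        bio[1] = True
        root[2] = True
        labels = cl.build_structure_labels(pore, bio, root)
        assert (labels[0] == cl.STRUCTURE_CODES["macropore"]).all()
        assert (labels[1] == cl.STRUCTURE_CODES["biopore"]).all()
        assert (labels[2] == cl.STRUCTURE_CODES["root_old"]).all()
        assert (labels[3:] == cl.STRUCTURE_CODES["matrix"]).all()

    def test_root_wins_inside_biopore(self):
        shape = (4, 4, 4)
        bio = np.ones(shape, bool)
        root = np.zeros(shape, bool)
        root[2, 2, 2] = True
        labels = cl.build_structure_labels(bio, bio, root)
        assert labels[2, 2, 2] == cl.STRUCTURE_CODES["root_old"]
        assert (labels[0, 0, 0] == cl.STRUCTURE_CODES["biopore"])

    def test_misaligned_shapes(self):
        with pytest.raises(ValueError):
            cl.build_structure_labels(np.zeros((4, 4, 4), bool),
                                      np.zeros((5, 4, 4), bool),
                                      np.zeros((4, 4, 4), bool))

    def test_flagship_code_counts_match_truth(self, flagship):
        truth = flagship["truth"]
        labels = flagship["labels1"]
        n = labels.size
        for name, truth_code in (("macropore", 1), ("biopore", 2), ("root_old", 3)):
            pred = (labels == cl.STRUCTURE_CODES[name]).sum() / n
            planted = (truth.labels_t1 == truth_code).sum() / n
            assert abs(pred - planted) <= 0.02  # within 2 pp of core volume


class TestTrajectories:
    def test_all_matrix(self):
        labels = np.zeros((6, 6, 6), np.uint8)
        nr = np.zeros((6, 6, 6), bool)
        nr[2, 2, 2] = True
        tf = cl.root_trajectory_fractions(nr, labels, 0.04)
        assert tf.percents["into_matrix"] == 100.0
        assert sum(tf.percents.values()) == pytest.approx(100.0, abs=0.01)

    def test_entirely_inside_biopore(self):
        labels = np.full((6, 6, 6), cl.STRUCTURE_CODES["biopore"], np.uint8)
        nr = np.ones((6, 6, 6), bool)
        tf = cl.root_trajectory_fractions(nr, labels, 0.04)
        assert tf.percents["into_biopore"] == 100.0

    def test_empty_mask_all_zero(self):
        tf = cl.root_trajectory_fractions(np.zeros((4, 4, 4), bool),
                                          np.zeros((4, 4, 4), np.uint8), 0.04)
        assert tf.total_volume_mm3 == 0.0
        assert all(v == 0 for v in tf.percents.values())

    def test_percent_sum_invariant(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, (10, 10, 10)).astype(np.uint8)
        nr = rng.random((10, 10, 10)) < 0.3
        tf = cl.root_trajectory_fractions(nr, labels, 0.04)
        assert sum(tf.percents.values()) == pytest.approx(100.0, abs=0.01)
        assert sum(tf.percents_3class.values()) == pytest.approx(100.0, abs=0.01)


class TestVoxelFeatures:
    def test_constant_volume_flat_features(self):
        X = cl.voxel_features(np.full((12, 12, 12), 57.0), scales=(1, 2))
        # gradient magnitude, laplacian, structure tensor, variance all zero
        names = cl.FEATURE_NAMES
        for s in range(2):
            for j, name in enumerate(names):
                col = X[:, s * len(names) + j]
                if name == "gaussian":
                    assert np.allclose(col, 57.0, atol=0.05)
                else:
                    assert np.allclose(col, 0.0, atol=0.05)

    def test_feature_count(self):
        X = cl.voxel_features(np.zeros((8, 8, 8)), scales=(1, 2, 4))
        assert X.shape == (512, 15)

    def test_variance_separates_smooth_from_speckle(self):
        rng = np.random.default_rng(0)
        smooth = np.full((16, 16, 16), 135.0)
        speckle = np.where(rng.random((16, 16, 16)) < 0.5, 90.0, 180.0)
        var_idx = list(cl.FEATURE_NAMES).index("local_variance")
        vs = cl.voxel_features(smooth, scales=(2,))[:, var_idx].mean()
        vp = cl.voxel_features(speckle, scales=(2,))[:, var_idx].mean()
        assert vp > 10 * max(vs, 1e-6)


class TestCastClassifier:
    def _separable(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        X = np.concatenate([
            rng.normal((0, 0), 0.05, (n, 2)),
            rng.normal((5, 0), 0.05, (n, 2)),
            rng.normal((0, 5), 0.05, (n, 2)),
        ])
        y = np.repeat([0, 1, 2], n)
        return X, y

    def test_separable_oob_below_one_percent(self):
        X, y = self._separable()
        _, oob = cl.train_cast_classifier(X, y, seed=0)
        assert oob <= 0.01

    def test_shuffled_labels_give_chance_error(self):
        X, y = self._separable(n=400)
        rng = np.random.default_rng(1)
        _, oob = cl.train_cast_classifier(X, rng.permutation(y), seed=0)
        assert oob == pytest.approx(2.0 / 3.0, abs=0.05)

    def test_single_class_rejected(self):
        X = np.zeros((50, 3))
        with pytest.raises(ValueError):
            cl.train_cast_classifier(X, np.zeros(50, int), seed=0)

    def test_seed_determinism(self):
        X, y = self._separable()
        c1, oob1 = cl.train_cast_classifier(X, y, seed=7)
        c2, oob2 = cl.train_cast_classifier(X, y, seed=7)
        assert oob1 == oob2
        grid = np.random.default_rng(0).normal(2, 2, (100, 2))
        assert np.array_equal(c1.predict(grid), c2.predict(grid))


class TestSegmentAttribution:
    def test_majority_vote_and_tie_break(self):
        # two blocks: one clearly smooth-bright (earthworm), one speckled
        rng = np.random.default_rng(0)
        gray = np.full((12, 24, 12), 180.0)
        gray[:, :10] = 200.0
        gray[:, 14:] = np.where(rng.random((12, 10, 12)) < 0.5, 90, 180)
        destroyed = np.zeros((12, 24, 12), bool)
        destroyed[2:10, 2:8] = True
        destroyed[2:10, 16:22] = True
        agent_truth = np.full(destroyed.shape, -1, np.int8)
        agent_truth[:, :12] = 0
        agent_truth[:, 12:] = 1
        # add a third class region so training is valid
        gray[0:2] = 180.0
        agent_truth[0:2] = 2
        train_sel = destroyed.copy()
        train_sel[0:2] = True
        idx = cl.sample_training_voxels(agent_truth, train_sel, fraction=0.2,
                                        min_per_class=50, rng=0)
        X = cl.voxel_features(gray, scales=(1, 2), mask=None)
        clf, _ = cl.train_cast_classifier(X[idx], agent_truth.ravel()[idx], seed=0)
        rep = cl.classify_destroyed_biopores(gray, destroyed, clf, 0.04, scales=(1, 2))
        agents = set(rep["agent"])
        assert "earthworm_cast" in agents and "mesofauna_cast" in agents
        assert (rep["vote_fraction"] >= 1 / 3).all()

    def test_empty_mask_empty_report(self):
        class Dummy:
            def predict(self, X):
                return np.zeros(len(X), int)

        rep = cl.classify_destroyed_biopores(np.zeros((8, 8, 8)),
                                             np.zeros((8, 8, 8), bool), Dummy(), 0.04)
        assert len(rep) == 0 and rep.attrs["per_agent"] == {}
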