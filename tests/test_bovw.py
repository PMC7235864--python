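import numpy as np
import pytest

from molarbovw.bovw import (
    BagOfVisualWords,
    build_vocabulary,
    encode,
    ensure_compatible,
    load_vocabulary,
    save_vocabulary,
)
from molarbovw.errors import CompatibilityError, CorruptionError, ParameterError

from .oracles import nearest_center_oracle


def _blobs(rng, centers, n_per, spread):
    pts = [c + rng.normal(0, spread, (n_per, len(c))) for c in centers]
    return np.vstack(pts)


class TestBuildVocabulary:
    def test_k_equals_n_gives_zero_inertia(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 10, (12, 5))
        vocab = build_vocabulary(X, k=12, seed=1)
        assert vocab.inertia == pytest.approx(0.0, abs=1e-9)
        # centers are a permutation of the inputs
        matched = {tuple(np.round(c, 9)) for c in vocab.centers}
        assert matched == {tuple(np.round(x, 9)) for x in X}

    def test_two_separated_clusters_recovered(self):
        rng = np.random.default_rng(3)
        c0, c1 = np.zeros(4), np.full(4, 50.0)
        X = _blobs(rng, [c0, c1], 20, 0.5)
        vocab = build_vocabulary(X, k=2, seed=2)
        means = np.array([X[:20].mean(axis=0), X[20:].mean(axis=0)])
        dists = [min(np.linalg.norm(c - m) for c in vocab.centers) for m in means]
        assert max(dists) < 0.1

    def test_fixed_point_of_assignment(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (60, 8))
        vocab = build_vocabulary(X, k=5, seed=4)
        labels = nearest_center_oracle(X, vocab.centers)
        # every point's nearest center (brute force) owns it; the center
        # is the mean of its members (Lloyd fixed point)
        for j in range(5):
            members = X[labels == j]
            if len(members):
                np.testing.assert_allclose(
                    vocab.centers[j], members.mean(axis=0), atol=1e-6
                )

    def test_inertia_monotone_nonincreasing(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (300, 16))
        vocab = build_vocabulary(X, k=20, seed=6)
        path = np.array(vocab.inertia_path)
        assert (np.diff(path) <= 1e-6 * path[0]).all()

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (200, 8))
        a = build_vocabulary(X, k=10, seed=3)
        b = build_vocabulary(X, k=10, seed=3)
        np.testing.assert_array_equal(a.centers, b.centers)
        assert a.inertia == b.inertia

    def test_fewer_points_than_k(self):
        with pytest.raises(ParameterError, match="smaller k"):
            build_vocabulary(np.zeros((5, 3)), k=10)

    def test_matches_sklearn_on_separated_blobs(self):
        """Independent cross-check: on well-separated data both solvers
        find the same optimum."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(11)
        centers = np.array([[0, 0], [40, 0], [0, 40], [40, 40]], dtype=float)
        X = _blobs(rng, centers, 30, 0.8)
        ours = build_vocabulary(X, k=4, seed=0)
        ref = KMeans(n_clusters=4, n_init=10, random_state=0).fit(X)
        assert ours.inertia == pytest.approx(ref.inertia_, rel=1e-6)


class TestEncode:
    def test_empty_descriptors(self):
        vocab = build_vocabulary(np.eye(4), k=2, seed=0)
        hist = encode(np.zeros((0, 4)), vocab)
        assert hist.counts.sum() == 0 and hist.n_descriptors == 0
        assert not hist.normalized

    def test_descriptors_equal_to_center(self):
        X = np.array([[0.0, 0.0], [10.0, 10.0]])
        vocab = build_vocabulary(X, k=2, seed=0)
        j = int(np.argmin(np.abs(vocab.centers[:, 0] - 10.0)))
        hist = encode(np.tile([10.0, 10.0], (5, 1)), vocab)
        assert hist.counts[j] == 5 and hist.counts.sum() == 5

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (30, 6))
        vocab = build_vocabulary(rng.normal(0, 1, (40, 6)), k=7, seed=seed)
        hist = encode(X, vocab)
        expected = np.bincount(nearest_center_oracle(X, vocab.centers), minlength=7)
        np.testing.assert_array_equal(hist.counts, expected)
        assert hist.counts.sum() == 30

    def test_normalized_sums_to_one(self):
        rng = np.random.default_rng(2)
        vocab = build_vocabulary(rng.normal(0, 1, (50, 4)), k=5, seed=1)
        hist = encode(rng.normal(0, 1, (17, 4)), vocab, normalize=True)
        assert hist.counts.sum() == pytest.approx(1.0, abs=1e-9)
        assert hist.normalized and hist.n_descriptors == 17

    def test_dimension_mismatch_names_both(self):
        vocab = build_vocabulary(np.random.default_rng(0).normal(0, 1, (9, 4)), k=3)
        with pytest.raises(CompatibilityError, match="4"):
            encode(np.zeros((2, 7)), vocab)


class TestPersistence:
    def test_roundtrip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(1)
        vocab = build_vocabulary(rng.normal(0, 1, (60, 8)), k=6, seed=2, method="SIFT")
        path = save_vocabulary(vocab, tmp_path / "v.bovw")
        loaded = load_vocabulary(path)
        np.testing.assert_array_equal(loaded.centers, vocab.centers)
        assert (loaded.k, loaded.d, loaded.method) == (6, 8, "SIFT")
        assert loaded.inertia == vocab.inertia

    def test_truncated_file_fails_closed(self, tmp_path):
        vocab = build_vocabulary(np.random.default_rng(0).normal(0, 1, (30, 4)), k=3)
        path = save_vocabulary(vocab, tmp_path / "v.bovw")
        path.write_bytes(path.read_bytes()[:-8])
        with pytest.raises(CorruptionError):
            load_vocabulary(path)

    def test_method_dimension_compatibility(self, tmp_path):
        vocab = build_vocabulary(
            np.random.default_rng(0).normal(0, 1, (200, 128)), k=4, method="SIFT"
        )
        with pytest.raises(CompatibilityError):
            ensure_compatible(vocab, "ORB", 32)


class TestEstimator:
    def test_fit_transform_shapes(self):
        rng = np.random.default_rng(4)
        bags = [rng.normal(0, 1, (rng.integers(5, 20), 8)) for _ in range(6)]
        bovw = BagOfVisualWords(n_words=10, seed=0)
        H = bovw.fit_transform(bags)
        assert H.shape == (6, 10)
        np.testing.assert_allclose(H.sum(axis=1), 1.0)

    def test_raw_counts_conserved(self):
        rng = np.random.default_rng(4)
        bags = [rng.normal(0, 1, (12, 8)) for _ in range(4)]
        bovw = BagOfVisualWords(n_words=5, seed=0, normalize=False).fit(bags)
        H = bovw.transform(bags)
        np.testing.assert_array_equal(H.sum(axis=1), [12, 12, 12, 12])

    def test_sklearn_clone_and_pipeline(self):
        from sklearn.base import clone
        from sklearn.pipeline import Pipeline
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(9)
        # two bag classes with disjoint descriptor clusters
        bags, y = [], []
        for i in range(20):
            center = np.zeros(6) if i % 2 else np.full(6, 30.0)
            bags.append(center + rng.normal(0, 0.5, (15, 6)))
            y.append(i % 2)
        est = BagOfVisualWords(n_words=4, seed=1)
        assert clone(est).get_params() == est.get_params()
        pipe = Pipeline(
            [("bovw", est), ("tree", DecisionTreeClassifier(random_state=0))]
        )
        pipe.fit(bags, y)
        assert pipe.score(bags, y) == 1.0

    def test_transform_before_fit_raises(self):
        with pytest.raises(ParameterError):
            BagOfVisualWords(n_words=3).transform([np.zeros((2, 4))])
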