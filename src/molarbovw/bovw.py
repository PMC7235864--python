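"""Visual vocabulary construction and bag-of-visual-words encoding.

All descriptors pooled over the training images are clustered with
K-means; the K cluster centers form the visual vocabulary (codebook).
Each image is then encoded as the histogram of its descriptors'
nearest-center assignments — a representation that keeps descriptor
*frequency* but discards position.

The clustering is Lloyd's algorithm with k-means++ initialisation.
Binary ORB descriptors are clustered in real space (bytes cast to
reals) with Euclidean distance, exactly like the float descriptors —
a deliberate, documented approximation that treats all extractors
uniformly.  Empty clusters are re-seeded from the point currently
farthest from its assigned center.  The per-iteration inertia trace is
recorded; Lloyd's updates guarantee it never increases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .errors import CompatibilityError, CorruptionError, ParameterError

__all__ = [
    "Vocabulary",
    "BovwHistogram",
    "build_vocabulary",
    "encode",
    "save_vocabulary",
    "load_vocabulary",
    "BagOfVisualWords",
]


@dataclass
class Vocabulary:
    """K cluster centers over descriptor space, plus fit metadata."""

    centers: np.ndarray  # K x d float64
    method: str
    kmeans_seed: int
    inertia: float
    inertia_path: tuple[float, ...] = ()
    n_iter: int = 0

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    @property
    def d(self) -> int:
        return self.centers.shape[1]


@dataclass
class BovwHistogram:
    """Length-K visual-word frequency vector for one image.

    ``counts`` holds raw integer counts when ``normalized`` is False and
    the L1-normalised frequencies otherwise.
    """

    counts: np.ndarray
    n_descriptors: int
    normalized: bool


def _nearest_centers(X: np.ndarray, centers: np.ndarray, chunk: int = 8192):
    """Index of the Euclidean-nearest center per row (ties -> lowest index)
    and the squared distance to it."""
    n = X.shape[0]
    labels = np.empty(n, dtype=np.int64)
    sqdist = np.empty(n, dtype=np.float64)
    for start in range(0, n, chunk):
        block = cdist(X[start : start + chunk], centers, metric="sqeuclidean")
        labels[start : start + chunk] = np.argmin(block, axis=1)
        sqdist[start : start + chunk] = block[
            np.arange(block.shape[0]), labels[start : start + chunk]
        ]
    return labels, sqdist


def build_vocabulary(
    descriptors: np.ndarray,
    k: int,
    seed: int = 0,
    method: str = "ORB",
    max_iter: int = 300,
    tol: float = 1e-4,
) -> Vocabulary:
    """Cluster pooled descriptors into a K-word visual vocabulary.

    Lloyd's algorithm, k-means++ init seeded by ``seed``; stops when the
    largest center shift drops below ``tol`` or after ``max_iter``
    iterations.  Deterministic for fixed inputs and seed.
    """
    X = np.asarray(descriptors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ParameterError(f"descriptor pool must be a non-empty 2-D array, got {X.shape}")
    n = X.shape[0]
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if n < k:
        raise ParameterError(
            f"only {n} pooled descriptors for k={k} words; use a smaller k "
            f"(the synthetic preset uses k=200, small runs k<=n)"
        )
    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    centers = centers.astype(np.float64)

    inertia_path: list[float] = []
    prev_inertia = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        labels, sqdist = _nearest_centers(X, centers)
        inertia = float(sqdist.sum())
        # Lloyd's updates cannot increase the objective
        assert inertia <= prev_inertia + 1e-6 * max(1.0, abs(prev_inertia))
        inertia_path.append(inertia)
        prev_inertia = inertia

        new_centers = centers.copy()
        counts = np.bincount(labels, minlength=k)
        sums = np.zeros_like(centers)
        np.add.at(sums, labels, X)
        nonempty = counts > 0
        new_centers[nonempty] = sums[nonempty] / counts[nonempty, None]

        empty = np.flatnonzero(~nonempty)
        if empty.size:
            # re-seed each empty cluster at a point currently farthest
            # from its assigned center (distinct point per empty cluster)
            far_order = np.argsort(-sqdist, kind="stable")
            for j, ci in enumerate(empty):
                new_centers[ci] = X[int(far_order[j])]

        shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
        centers = new_centers
        if shift < tol:
            break

    _, sqdist = _nearest_centers(X, centers)
    final_inertia = float(sqdist.sum())
    inertia_path.append(final_inertia)
    return Vocabulary(
        centers=centers,
        method=method.upper(),
        kmeans_seed=int(seed),
        inertia=final_inertia,
        inertia_path=tuple(inertia_path),
        n_iter=n_iter,
    )


def encode(
    descriptors: np.ndarray, vocab: Vocabulary, normalize: bool = False
) -> BovwHistogram:
    """Histogram of nearest-center assignments for one image's descriptors.

    Ties break to the lowest center index.  A zero-descriptor image
    yields the all-zero histogram with ``normalized`` forced False.
    """
    X = np.asarray(descriptors, dtype=np.float64)
    if X.ndim != 2:
        raise ParameterError(f"descriptors must be 2-D, got shape {X.shape}")
    if X.shape[0] == 0:
        return BovwHistogram(
            counts=np.zeros(vocab.k, dtype=np.int64), n_descriptors=0, normalized=False
        )
    if X.shape[1] != vocab.d:
        raise CompatibilityError(
            f"descriptor dimension {X.shape[1]} does not match vocabulary dimension {vocab.d}"
        )
    labels, _ = _nearest_centers(X, vocab.centers)
    counts = np.bincount(labels, minlength=vocab.k).astype(np.int64)
    if normalize:
        return BovwHistogram(
            counts=counts / counts.sum(), n_descriptors=int(X.shape[0]), normalized=True
        )
    return BovwHistogram(counts=counts, n_descriptors=int(X.shape[0]), normalized=False)


def save_vocabulary(vocab: Vocabulary, path: str | Path) -> Path:
    """Write a ``.bovw`` file: one JSON header line + little-endian
    float64 row-major center block."""
    path = Path(path)
    centers = np.ascontiguousarray(vocab.centers, dtype="<f8")
    header = {
        "format": "bovw-vocabulary",
        "version": 1,
        "k": vocab.k,
        "d": vocab.d,
        "method": vocab.method,
        "kmeans_seed": vocab.kmeans_seed,
        "inertia": vocab.inertia,
        "n_iter": vocab.n_iter,
        "dtype": "<f8",
        "n_bytes": centers.nbytes,
    }
    with open(path, "wb") as fh:
        fh.write(json.dumps(header, sort_keys=True).encode("utf-8") + b"\n")
        fh.write(centers.tobytes())
    return path


def load_vocabulary(path: str | Path) -> Vocabulary:
    path = Path(path)
    with open(path, "rb") as fh:
        try:
            header = json.loads(fh.readline().decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise CorruptionError(f"unreadable vocabulary header in {path}") from exc
        if header.get("format") != "bovw-vocabulary":
            raise CorruptionError(f"{path} is not a vocabulary file")
        blob = fh.read()
    k, d = int(header["k"]), int(header["d"])
    if len(blob) != int(header["n_bytes"]) or len(blob) != k * d * 8:
        raise CorruptionError(
            f"{path}: center block has {len(blob)} bytes, header promises {header['n_bytes']}"
        )
    centers = np.frombuffer(blob, dtype="<f8").reshape(k, d).astype(np.float64)
    return Vocabulary(
        centers=centers,
        method=header["method"],
        kmeans_seed=int(header["kmeans_seed"]),
        inertia=float(header["inertia"]),
        n_iter=int(header.get("n_iter", 0)),
    )


def ensure_compatible(vocab: Vocabulary, method: str, d: int) -> None:
    """Raise unless the vocabulary matches the extractor's method and dimension."""
    if vocab.method != method.upper() or vocab.d != d:
        raise CompatibilityError(
            f"vocabulary ({vocab.method}, d={vocab.d}) incompatible with "
            f"descriptors ({method.upper()}, d={d})"
        )


class BagOfVisualWords:
    """sklearn-style transformer: descriptor bags -> visual-word histograms.

    ``fit`` pools the per-image descriptor arrays and clusters them into
    ``n_words`` centers; ``transform`` encodes each bag as a length-K
    histogram (L1-normalised by default so images with different
    keypoint counts are comparable).

    Fitted attributes: ``vocabulary_``, ``cluster_centers_``,
    ``inertia_``, ``inertia_path_``, ``n_iter_``.
    """

    def __init__(
        self,
        n_words: int = 2800,
        seed: int = 0,
        normalize: bool = True,
        method: str = "ORB",
        max_iter: int = 300,
        tol: float = 1e-4,
    ):
        self.n_words = n_words
        self.seed = seed
        self.normalize = normalize
        self.method = method
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_words": self.n_words,
            "seed": self.seed,
            "normalize": self.normalize,
            "method": self.method,
            "max_iter": self.max_iter,
            "tol": self.tol,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    @staticmethod
    def _pool(X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return np.asarray(X, dtype=np.float64)
        bags = [np.asarray(b, dtype=np.float64) for b in X if len(b)]
        if not bags:
            raise ParameterError("no descriptors in any bag")
        return np.vstack(bags)

    def fit(self, X, y=None):
        pooled = self._pool(X)
        self.vocabulary_ = build_vocabulary(
            pooled,
            k=self.n_words,
            seed=self.seed,
            method=self.method,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        self.cluster_centers_ = self.vocabulary_.centers
        self.inertia_ = self.vocabulary_.inertia
        self.inertia_path_ = self.vocabulary_.inertia_path
        self.n_iter_ = self.vocabulary_.n_iter
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "vocabulary_"):
            raise ParameterError("BagOfVisualWords is not fitted; call fit first")
        if isinstance(X, np.ndarray) and X.ndim == 2:
            X = [X]
        rows = [
            encode(bag, self.vocabulary_, normalize=self.normalize).counts for bag in X
        ]
        return np.vstack([np.asarray(r, dtype=np.float64) for r in rows])

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
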