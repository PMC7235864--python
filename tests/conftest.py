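import numpy as np
import pytest

from molarbovw import (
    ExtractorConfig,
    SyntheticConfig,
    extract_features,
    generate_dataset,
    make_roi_mask,
    preprocess_chain,
)
from molarbovw.pipeline import stage_seed


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """Nine half-scale phantoms, three per class."""
    return generate_dataset(SyntheticConfig(n_images=9, height=600, width=1200, seed=7))


@pytest.fixture(scope="session")
def preset_run():
    """The full synthetic study: n=150 reference-size phantoms (seed 42),
    preprocessed, masked, ORB-extracted.

    Session-scoped because generation plus extraction dominates the
    suite's runtime; the histograms, labels and per-image keypoint
    counts are shared by every test that needs the study conditions.
    """
    config = SyntheticConfig(n_images=150, seed=42)
    dataset = generate_dataset(config)
    mask = make_roi_mask(config.height, config.width)
    extractor = ExtractorConfig()
    matrices, labels, kp_counts = [], [], []
    for item in dataset:
        edge = preprocess_chain(item.image)
        keypoints, matrix = extract_features(edge, mask, extractor)
        matrices.append(matrix)
        labels.append(item.label)
        kp_counts.append(len(keypoints))
    return {
        "config": config,
        "matrices": matrices,
        "labels": np.array(labels),
        "keypoint_counts": np.array(kp_counts),
        "vocab_seed": stage_seed(42, "vocabulary"),
        "fold_seed": stage_seed(42, "folds"),
    }
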