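import numpy as np
import pytest

from molarbovw.errors import CapabilityError, CorruptionError, ParameterError
from molarbovw.features import (
    DESCRIPTOR_DIMENSIONS,
    ExtractorConfig,
    KeypointDescriptorExtractor,
    available_methods,
    batch_extract,
    extract_features,
    load_descriptors,
    save_descriptors,
)
from molarbovw.preprocess import preprocess_chain
from molarbovw.roi import RoiMask, RoiSpec, make_roi_mask


def _textured_image(seed=0, shape=(600, 1200)):
    """Raw phantom (no edge chain) — high texture for reliable detections."""
    from molarbovw.synthetic import SyntheticConfig, generate_dataset

    return generate_dataset(
        SyntheticConfig(n_images=3, height=shape[0], width=shape[1], seed=seed)
    )


class TestExtract:
    def test_constant_image_yields_nothing(self):
        img = np.full((600, 1200), 80, dtype=np.uint8)
        mask = make_roi_mask(600, 1200)
        kps, mat = extract_features(img, mask, ExtractorConfig())
        assert kps == [] and mat.descriptors.shape == (0, 32)

    def test_all_false_mask_yields_nothing(self):
        img = _textured_image()[0].image
        empty = RoiMask(mask=np.zeros(img.shape, dtype=bool))
        kps, mat = extract_features(img, empty, ExtractorConfig())
        assert kps == [] and mat.n == 0

    @pytest.mark.parametrize("method", ["ORB", "SIFT"])
    def test_mask_containment_and_dimension(self, method):
        mask = make_roi_mask(600, 1200)
        for item in _textured_image(seed=4):
            kps, mat = extract_features(item.image, mask, ExtractorConfig(method=method))
            assert mat.d == DESCRIPTOR_DIMENSIONS[method]
            assert mat.n == len(kps)
            for k in kps:
                assert mask.mask[int(round(k.row)), int(round(k.col))]

    def test_surf_capability_error(self):
        img = np.zeros((600, 1200), dtype=np.uint8)
        with pytest.raises(CapabilityError):
            extract_features(img, make_roi_mask(600, 1200), ExtractorConfig(method="SURF"))
        assert "SURF" not in available_methods()

    def test_unknown_method(self):
        with pytest.raises(ParameterError):
            ExtractorConfig(method="BRISK").validate()

    def test_deterministic(self):
        img = _textured_image(seed=2)[0].image
        mask = make_roi_mask(600, 1200)
        _, a = extract_features(img, mask, ExtractorConfig())
        _, b = extract_features(img, mask, ExtractorConfig())
        np.testing.assert_array_equal(a.descriptors, b.descriptors)

    def test_max_keypoints_cap(self):
        img = _textured_image(seed=3)[0].image
        mask = make_roi_mask(600, 1200)
        kps, mat = extract_features(img, mask, ExtractorConfig(max_keypoints=7))
        assert len(kps) <= 7 and mat.n == len(kps)

    def test_keypoint_near_each_affected_site(self):
        """At default contrast every affected molar attracts a keypoint
        within 15 px of its ground-truth centre (reference-size phantom)."""
        from molarbovw.synthetic import SyntheticConfig, generate_dataset

        ds = generate_dataset(SyntheticConfig(n_images=3, seed=7))
        mask = make_roi_mask(1200, 2400)
        for item in ds:
            edge = preprocess_chain(item.image)
            kps, _ = extract_features(edge, mask, ExtractorConfig())
            pts = np.array([(k.row, k.col) for k in kps]) if kps else np.zeros((0, 2))
            for s in item.ground_truth_sites:
                if not s.present:
                    continue
                d = np.hypot(pts[:, 0] - s.row, pts[:, 1] - s.col).min()
                assert d <= 15.0

    def test_rotation_robustness_of_keypoint_count(self):
        img = _textured_image(seed=5, shape=(600, 600))[0].image
        spec = RoiSpec(0, 600, 0, 600, 600, 600)
        mask = make_roi_mask(600, 600, spec)
        kps, _ = extract_features(img, mask, ExtractorConfig(max_keypoints=10000))
        kps_rot, _ = extract_features(
            np.ascontiguousarray(np.rot90(img)), mask, ExtractorConfig(max_keypoints=10000)
        )
        n, m = len(kps), len(kps_rot)
        assert n > 0 and abs(n - m) / max(n, m) < 0.20


class TestBatch:
    def test_three_image_manifest(self):
        items = _textured_image(seed=6)
        manifest = [(d.image, d.label) for d in items]
        mats, log = batch_extract(
            manifest, roi_spec=RoiSpec(), config=ExtractorConfig(), use_edge_image=False
        )
        assert len(mats) == 3
        assert all("error" not in e for e in log)

    def test_blank_image_flagged_others_unaffected(self):
        items = _textured_image(seed=8)
        blank = np.full_like(items[0].image, 50)
        manifest = [(items[0].image, "a"), (blank, "b"), (items[1].image, "c")]
        mats, log = batch_extract(manifest, config=ExtractorConfig(), use_edge_image=False)
        assert mats[1].n == 0
        assert any(e.get("warning") == "zero keypoints" and e["index"] == 1 for e in log)
        assert mats[0].n > 0 and mats[2].n > 0

    def test_batch_deterministic(self):
        items = _textured_image(seed=9)
        manifest = [(d.image, d.label) for d in items]
        a, _ = batch_extract(manifest, config=ExtractorConfig(), use_edge_image=False)
        b, _ = batch_extract(manifest, config=ExtractorConfig(), use_edge_image=False)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.descriptors, y.descriptors)


class TestPersistence:
    def test_bit_exact_roundtrip(self, tmp_path):
        items = _textured_image(seed=1)
        mats, _ = batch_extract(
            [(d.image, d.label) for d in items], config=ExtractorConfig(), use_edge_image=False
        )
        path = save_descriptors(mats, tmp_path / "run.desc")
        loaded = load_descriptors(path)
        assert len(loaded) == len(mats)
        for x, y in zip(mats, loaded):
            np.testing.assert_array_equal(x.descriptors, y.descriptors)
            assert x.method == y.method

    def test_truncated_file_fails_closed(self, tmp_path):
        items = _textured_image(seed=1)
        mats, _ = batch_extract(
            [(d.image, d.label) for d in items], config=ExtractorConfig(), use_edge_image=False
        )
        path = save_descriptors(mats, tmp_path / "run.desc")
        data = path.read_bytes()
        path.write_bytes(data[: len(data) - 16])
        with pytest.raises(CorruptionError):
            load_descriptors(path)


class TestSklearnAdapter:
    def test_transform_shapes_and_params(self):
        items = _textured_image(seed=2)
        ext = KeypointDescriptorExtractor(method="ORB", max_keypoints=50, use_edge_image=False)
        assert ext.get_params()["max_keypoints"] == 50
        ext.set_params(max_keypoints=40)
        bags = ext.fit_transform([d.image for d in items])
        assert len(bags) == 3
        for bag in bags:
            assert bag.shape[1] == 32 and bag.shape[0] <= 40
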