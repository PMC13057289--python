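"""Dataset indexing, stratified splitting, preprocessing and augmentation."""

from pathlib import Path

import numpy as np
import pytest
from PIL import Image

from leaffusionnet import data_pipeline as dp


@pytest.fixture()
def toy_tree(tmp_path):
    """Two-class folder tree with 3 + 2 tiny images."""
    rng = np.random.default_rng(0)
    for cname, n in (("alpha", 3), ("beta", 2)):
        d = tmp_path / cname
        d.mkdir()
        for i in range(n):
            arr = (rng.random((8, 8, 3)) * 255).astype(np.uint8)
            Image.fromarray(arr).save(d / f"img_{i}.png")
    return tmp_path


class TestIndexDataset:
    def test_enumeration_and_class_order(self, toy_tree):
        idx = dp.index_dataset(toy_tree)
        assert len(idx) == 5
        assert idx.class_names == ["alpha", "beta"]
        assert [r[2] for r in idx.records] == [0, 0, 0, 1, 1]

    def test_reindexing_is_deterministic(self, toy_tree):
        a = dp.index_dataset(toy_tree)
        b = dp.index_dataset(toy_tree)
        assert [r[0] for r in a.records] == [r[0] for r in b.records]

    def test_corrupt_file_skipped_and_counted(self, toy_tree):
        (toy_tree / "alpha" / "broken.png").write_bytes(b"\x89PNG\r\n\x1a\nnot")
        idx = dp.index_dataset(toy_tree)
        assert len(idx) == 5
        assert idx.n_skipped == 1

    def test_single_class_rejected(self, tmp_path):
        d = tmp_path / "only"
        d.mkdir()
        Image.fromarray(np.zeros((4, 4, 3), np.uint8)).save(d / "x.png")
        with pytest.raises(ValueError, match="two class"):
            dp.index_dataset(tmp_path)


class TestStratifiedSplit:
    def test_four_classes_of_25_split_exactly_16_4_5(self):
        labels = np.repeat(np.arange(4), 25)
        spec = dp.stratified_split_labels(labels, list("abcd"), seed=0)
        assert (len(spec.train), len(spec.val), len(spec.test)) == (64, 16, 20)
        for c in range(4):
            counts = [np.sum(labels[ids] == c)
                      for ids in (spec.train, spec.val, spec.test)]
            assert counts == [16, 4, 5]

    def test_unbalanced_proportions_within_one_sample_per_class(self):
        sizes = [10, 23, 37, 50, 64, 81, 100]
        labels = np.concatenate([np.full(n, c) for c, n in enumerate(sizes)])
        spec = dp.stratified_split_labels(labels, [str(c) for c in range(7)], seed=1)
        for c, n in enumerate(sizes):
            n_test = np.sum(labels[spec.test] == c)
            n_val = np.sum(labels[spec.val] == c)
            assert abs(n_test - 0.2 * n) <= 1
            assert abs(n_val - 0.16 * n) <= 1

    def test_seed_determinism_and_sensitivity(self):
        labels = np.repeat(np.arange(4), 30)
        s1 = dp.stratified_split_labels(labels, list("abcd"), seed=5)
        s2 = dp.stratified_split_labels(labels, list("abcd"), seed=5)
        s3 = dp.stratified_split_labels(labels, list("abcd"), seed=6)
        assert s1.as_dict() == s2.as_dict()
        assert s1.train != s3.train

    def test_no_leakage_between_splits(self):
        labels = np.repeat(np.arange(3), 17)
        spec = dp.stratified_split_labels(labels, list("abc"), seed=2)
        sets = [set(spec.train), set(spec.val), set(spec.test)]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
        assert sets[0] | sets[1] | sets[2] == set(range(len(labels)))

    def test_tiny_class_rejected_by_name(self):
        labels = np.array([0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="beta"):
            dp.stratified_split_labels(labels, ["alpha", "beta"])

    def test_every_split_nonempty_for_minimal_class(self):
        labels = np.array([0] * 3 + [1] * 25)
        spec = dp.stratified_split_labels(labels, ["a", "b"], seed=0)
        for ids in (spec.train, spec.val, spec.test):
            assert np.sum(labels[ids] == 0) >= 1


class TestPreprocess:
    def test_scaling_endpoints(self, tmp_path):
        for val, expect in ((255, 1.0), (0, 0.0)):
            p = tmp_path / f"v{val}.png"
            Image.fromarray(np.full((10, 10, 3), val, np.uint8)).save(p)
            out = dp.preprocess(p, side=8)
            assert out.shape == (8, 8, 3)
            np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_bilinear_upsampling_matches_hand_grid(self):
        # 2x2 checkerboard -> 4x4, pixel-centre aligned bilinear
        img = np.array([[1.0, 0.0], [0.0, 1.0]])[..., None].repeat(3, axis=2)
        out = dp.resize_bilinear(img, 4)

        def oracle(i, j):
            # output centre (i+.5)/4 maps to input coordinate (i+.5)/2-.5
            yi, xi = (i + 0.5) / 2 - 0.5, (j + 0.5) / 2 - 0.5
            y0, x0 = int(np.clip(np.floor(yi), 0, 0)), int(np.clip(np.floor(xi), 0, 0))
            fy, fx = np.clip(yi - y0, 0, 1), np.clip(xi - x0, 0, 1)
            g = img[..., 0]
            return ((1 - fy) * (1 - fx) * g[y0, x0] + (1 - fy) * fx * g[y0, x0 + 1]
                    + fy * (1 - fx) * g[y0 + 1, x0] + fy * fx * g[y0 + 1, x0 + 1])

        expected = np.array([[oracle(i, j) for j in range(4)] for i in range(4)])
        np.testing.assert_allclose(out[..., 0], expected, atol=1e-12)

    def test_non_image_rejected(self, tmp_path):
        p = tmp_path / "not_an_image.png"
        p.write_text("plain text")
        with pytest.raises(ValueError, match="decode"):
            dp.preprocess(p)


class TestAugment:
    def test_double_flip_restores_image(self, rng):
        img = rng.random((9, 9, 3))
        once = dp.augment(img, rng, flip=True, angle_deg=0.0, zoom=1.0)
        twice = dp.augment(once, rng, flip=True, angle_deg=0.0, zoom=1.0)
        np.testing.assert_array_equal(twice, img)

    def test_identity_parameters_are_identity(self, rng):
        img = rng.random((12, 12, 3))
        out = dp.augment(img, rng, flip=False, angle_deg=0.0, zoom=1.0)
        np.testing.assert_array_equal(out, img)

    def test_forced_flip_reverses_columns(self, rng):
        img = np.arange(27, dtype=float).reshape(3, 3, 3) / 27.0
        out = dp.augment(img, rng, flip=True, angle_deg=0.0, zoom=1.0)
        np.testing.assert_array_equal(out, img[:, ::-1])

    def test_pixel_range_preserved(self, rng):
        img = rng.random((16, 16, 3))
        for _ in range(10):
            out = dp.augment(img, rng)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_rotation_moves_off_axis_mass(self, rng):
        img = np.zeros((15, 15, 1))
        img[7, 11, 0] = 1.0
        out = dp.augment(img, rng, flip=False, angle_deg=90.0, zoom=1.0)
        # a quarter turn about the centre maps column offset to row offset
        assert out[:, :, 0].max() > 0.5
        peak = np.unravel_index(out[:, :, 0].argmax(), (15, 15))
        assert peak in ((11, 7), (3, 7))


def test_split_manifest_roundtrip(toy_tree, tmp_path):
    idx = dp.index_dataset(toy_tree)
    labels = np.repeat([0, 1], [3, 2])
    np.testing.assert_array_equal(idx.labels, labels)
    spec = dp.SplitSpec(train=[0, 1, 3], val=[2], test=[4], seed=0)
    out = tmp_path / "manifest.csv"
    dp.write_split_manifest(idx, spec, out)
    lines = out.read_text().strip().splitlines()
    assert len(lines) == 6
    assert lines[0] == "path,class_name,class_id,split"


def test_load_split_arrays_shapes(toy_tree):
    idx = dp.index_dataset(toy_tree)
    spec = dp.SplitSpec(train=[0, 3], val=[1, 4], test=[2], seed=0)
    arrays = dp.load_split_arrays(idx, spec, side=8)
    assert arrays["train"][0].shape == (2, 8, 8, 3)
    np.testing.assert_array_equal(arrays["test"][1], [0])
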