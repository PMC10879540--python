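"""Folder ingestion, augmentation, splitting, and the synthetic generator."""

import numpy as np
import pytest
from PIL import Image

from ercpnet import (AugmentConfig, SyntheticSpec, augment_image,
                     generate_synthetic_dataset, load_image_folder,
                     save_image_folder, split_dataset)
from ercpnet import data as data_mod


def write_folder(root, classes, per_class=3, size=16):
    rng = np.random.default_rng(0)
    for cls in classes:
        d = root / cls
        d.mkdir(parents=True)
        for i in range(per_class):
            arr = (rng.random((size, size, 3)) * 255).astype(np.uint8)
            Image.fromarray(arr).save(d / f"img_{i}.png")


class TestFolderLoader:
    def test_enumeration_and_labels(self, tmp_path):
        write_folder(tmp_path, ["healthy", "rust"], per_class=3)
        ds = load_image_folder(str(tmp_path))
        assert len(ds) == 6
        assert sorted(set(ds.labels())) == [0, 1]

    def test_vocabulary_is_lexicographic(self, tmp_path):
        write_folder(tmp_path, ["ba", "ab"])
        ds = load_image_folder(str(tmp_path))
        assert ds.label_names == ["ab", "ba"]

    def test_reload_gives_identical_order(self, tmp_path):
        write_folder(tmp_path, ["a", "b"])
        d1 = load_image_folder(str(tmp_path))
        d2 = load_image_folder(str(tmp_path))
        for (i1, l1), (i2, l2) in zip(d1.items, d2.items):
            assert l1 == l2
            np.testing.assert_array_equal(i1, i2)

    def test_resize_and_range(self, tmp_path):
        write_folder(tmp_path, ["a"], size=20)
        ds = load_image_folder(str(tmp_path), image_size=8)
        img, _ = ds.items[0]
        assert img.shape == (3, 8, 8)
        assert img.min() >= 0 and img.max() <= 1

    def test_empty_class_directory_errors(self, tmp_path):
        write_folder(tmp_path, ["a"])
        (tmp_path / "empty").mkdir()
        with pytest.raises(ValueError, match="no images"):
            load_image_folder(str(tmp_path))

    def test_unreadable_file_errors_with_path(self, tmp_path):
        d = tmp_path / "a"
        d.mkdir()
        (d / "broken.png").write_bytes(b"not an image")
        with pytest.raises(ValueError, match="broken.png"):
            load_image_folder(str(tmp_path))

    def test_folder_roundtrip(self, tmp_path, small_dataset):
        save_image_folder(small_dataset, str(tmp_path / "out"))
        ds = load_image_folder(str(tmp_path / "out"))
        assert len(ds) == len(small_dataset)
        assert ds.num_classes == small_dataset.num_classes
        # pixel data survives the 8-bit round trip to within quantization
        np.testing.assert_allclose(ds.items[0][0], small_dataset.items[0][0],
                                   atol=1 / 255 + 1e-9)


class TestAugmentation:
    def test_identity_when_all_transforms_off(self, rng):
        cfg = AugmentConfig(p_hflip=0, p_vflip=0, max_rotation_deg=0, noise_sigma=0)
        img = rng.random((3, 8, 8))
        np.testing.assert_array_equal(augment_image(img, cfg, rng), img)

    def test_forced_flips_are_involutions(self, rng):
        cfg = AugmentConfig(p_hflip=1, p_vflip=1, max_rotation_deg=0, noise_sigma=0)
        img = rng.random((3, 8, 8))
        twice = augment_image(augment_image(img, cfg, rng), cfg, rng)
        np.testing.assert_allclose(twice, img)

    def test_shape_and_range_preserved(self, rng):
        cfg = AugmentConfig()
        img = rng.random((3, 12, 12))
        out = augment_image(img, cfg, rng)
        assert out.shape == img.shape
        assert out.min() >= 0 and out.max() <= 1

    def test_out_of_range_input_rejected(self, rng):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            augment_image(np.full((3, 4, 4), 1.5), AugmentConfig(), rng)

    def test_rotation_angles_uniform_on_interval(self, rng, monkeypatch):
        angles = []

        def fake_rotate(arr, angle, **kw):
            angles.append(angle)
            return arr

        monkeypatch.setattr(data_mod.ndimage, "rotate", fake_rotate)
        cfg = AugmentConfig(p_hflip=0, p_vflip=0, noise_sigma=0)
        img = np.zeros((3, 2, 2))
        for _ in range(2000):
            augment_image(img, cfg, rng)
        angles = np.array(angles)
        assert angles.min() >= 0 and angles.max() <= 35
        # mean of U(0, 35) is 17.5; allow 3 standard errors
        se = 35 / np.sqrt(12) / np.sqrt(len(angles))
        assert abs(angles.mean() - 17.5) < 3 * se

    def test_determinism_under_same_generator_state(self):
        cfg = AugmentConfig()
        img = np.random.default_rng(3).random((3, 8, 8))
        a = augment_image(img, cfg, np.random.default_rng(5))
        b = augment_image(img, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestSplit:
    @pytest.mark.parametrize("n,expected", [
        (100, (60, 20, 20)),
        (10, (6, 2, 2)),
        (11, (7, 2, 2)),
    ])
    def test_split_counts(self, n, expected):
        ds = generate_synthetic_dataset(
            SyntheticSpec(num_classes=2, per_class=n, image_size=32, seed=0))
        # restrict to one class to test the per-class rounding rule
        one = ds.subset(np.flatnonzero(ds.labels() == 0))
        tr, va, te = split_dataset(one, seed=1)
        assert (len(tr), len(va), len(te)) == expected

    def test_disjoint_exhaustive_stratified(self, small_dataset):
        tr, va, te = split_dataset(small_dataset, seed=4)
        assert len(tr) + len(va) + len(te) == len(small_dataset)
        for cls in range(small_dataset.num_classes):
            n_tr = (tr.labels() == cls).sum()
            n_va = (va.labels() == cls).sum()
            n_te = (te.labels() == cls).sum()
            assert (n_tr, n_va, n_te) == (8, 2, 2)   # 12 per class at 6:2:2
        # disjointness via pixel identity: every source image lands exactly once
        def keys(ds):
            return {arr.tobytes() for arr, _ in ds.items}
        all_keys = keys(tr) | keys(va) | keys(te)
        assert len(all_keys) == len(small_dataset)

    def test_small_class_rejected(self, tmp_path):
        write_folder(tmp_path, ["a"], per_class=2)
        ds = load_image_folder(str(tmp_path))
        with pytest.raises(ValueError, match="stratify"):
            split_dataset(ds)

    def test_empty_dataset_rejected(self, small_dataset):
        empty = small_dataset.subset([])
        with pytest.raises(ValueError, match="empty"):
            split_dataset(empty)


class TestSyntheticGenerator:
    def test_balanced_and_in_range(self):
        spec = SyntheticSpec(num_classes=4, per_class=10, image_size=32, seed=2)
        ds = generate_synthetic_dataset(spec)
        assert len(ds) == 40
        counts = np.bincount(ds.labels(), minlength=4)
        assert (counts == 10).all()
        imgs = ds.images()
        assert imgs.min() >= 0 and imgs.max() <= 1
        assert imgs.shape[1:] == (3, 32, 32)

    def test_byte_identical_under_same_spec(self):
        spec = SyntheticSpec(num_classes=3, per_class=4, image_size=32, seed=5)
        a = generate_synthetic_dataset(spec)
        b = generate_synthetic_dataset(spec)
        assert a.images().tobytes() == b.images().tobytes()

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            SyntheticSpec(image_size=8)

    def test_classes_separable_by_color_histogram(self):
        """Independent sanity oracle: a nearest-centroid classifier on
        per-channel color histograms must separate the classes."""
        spec = SyntheticSpec(num_classes=4, per_class=64, image_size=64, seed=13)
        ds = generate_synthetic_dataset(spec)
        tr, va, te = split_dataset(ds, seed=13)

        def histogram(img, bins=16):
            return np.concatenate([np.histogram(img[c], bins=bins, range=(0, 1),
                                                density=True)[0] for c in range(3)])

        feats_tr = np.stack([histogram(im) for im, _ in tr.items])
        centroids = np.stack([feats_tr[tr.labels() == k].mean(axis=0)
                              for k in range(4)])
        feats_te = np.stack([histogram(im) for im, _ in te.items])
        preds = np.linalg.norm(feats_te[:, None] - centroids[None], axis=2).argmin(axis=1)
        acc = (preds == te.labels()).mean()
        assert acc > 0.9
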