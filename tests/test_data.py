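"""Synthetic rendering, folder loading, preprocessing and augmentation."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from PIL import Image

from swinpoly.data import (CLASSES_8, AugmentationPolicy, SyntheticSpec,
                           augment, class_weights, generate_synthetic_dataset,
                           load_image_folder, preprocess)


def tree_hashes(root: Path) -> dict[str, str]:
    return {str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(root.rglob("*.png"))}


class TestGenerator:
    def test_counts_and_layout(self, mini_dataset):
        spec, root, manifest = mini_dataset
        assert len(manifest.records) == 4 * (6 + 2 + 4)
        assert manifest.class_names == ["CNV", "DME", "DRUSEN", "NORMAL"]
        train_files = list((root / "train").rglob("*.png"))
        assert len(train_files) == 24
        assert (root / "manifest.csv").exists()

    def test_deterministic_bytes(self, tmp_path):
        spec = SyntheticSpec(images_per_class={"train": 2, "test": 1},
                             image_size=64, seed=5)
        generate_synthetic_dataset(spec, tmp_path / "a")
        generate_synthetic_dataset(spec, tmp_path / "b")
        assert tree_hashes(tmp_path / "a") == tree_hashes(tmp_path / "b")

    def test_seed_changes_output(self, tmp_path):
        a = SyntheticSpec(images_per_class={"train": 1}, image_size=64, seed=1)
        b = SyntheticSpec(images_per_class={"train": 1}, image_size=64, seed=2)
        generate_synthetic_dataset(a, tmp_path / "a")
        generate_synthetic_dataset(b, tmp_path / "b")
        assert tree_hashes(tmp_path / "a") != tree_hashes(tmp_path / "b")

    def test_eight_class_set(self, tmp_path):
        spec = SyntheticSpec(classes=CLASSES_8,
                             images_per_class={"train": 1}, image_size=64)
        manifest = generate_synthetic_dataset(spec, tmp_path)
        assert manifest.class_names == sorted(CLASSES_8)
        assert len(manifest.records) == 8

    def test_splits_are_disjoint(self, mini_dataset):
        _, _, manifest = mini_dataset
        assert not manifest.records["path"].duplicated().any()


class TestLoader:
    def test_roundtrip_of_generated_tree(self, mini_dataset):
        _, root, manifest = mini_dataset
        loaded = load_image_folder(root)
        assert loaded.class_names == manifest.class_names
        for split in ("train", "val", "test"):
            assert len(loaded.subset(split)) == len(manifest.subset(split))

    def test_classes_sorted_lexicographically(self, tmp_path):
        for cls in ("NORMAL", "CNV", "DRUSEN", "DME"):
            d = tmp_path / "train" / cls
            d.mkdir(parents=True)
            Image.new("L", (8, 8)).save(d / "x.png")
        manifest = load_image_folder(tmp_path)
        assert manifest.class_names == ["CNV", "DME", "DRUSEN", "NORMAL"]

    def test_mixed_case_extensions_discovered(self, tmp_path):
        d = tmp_path / "train" / "CNV"
        d.mkdir(parents=True)
        Image.new("L", (8, 8)).save(d / "a.png")
        Image.new("L", (8, 8)).save(d / "b.JPEG")
        (tmp_path / "train" / "DME").mkdir()
        Image.new("L", (8, 8)).save(tmp_path / "train" / "DME" / "c.jpg")
        manifest = load_image_folder(tmp_path)
        assert len(manifest.subset("train")) == 3

    def test_flat_layout_treated_as_train(self, tmp_path):
        d = tmp_path / "CNV"
        d.mkdir()
        Image.new("L", (8, 8)).save(d / "a.png")
        manifest = load_image_folder(tmp_path)
        assert len(manifest.subset("train")) == 1

    def test_empty_class_warns(self, tmp_path):
        (tmp_path / "train" / "CNV").mkdir(parents=True)
        (tmp_path / "train" / "DME").mkdir()
        Image.new("L", (8, 8)).save(tmp_path / "train" / "DME" / "a.png")
        with pytest.warns(UserWarning, match="no images"):
            load_image_folder(tmp_path)

    def test_no_classes_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no class"):
            load_image_folder(tmp_path)


class TestPreprocess:
    def test_resize_rule(self, tmp_path):
        path = tmp_path / "img.png"
        Image.new("L", (512, 496), color=128).save(path)
        out = preprocess(path, size=224)
        assert out.shape == (224, 224, 1)

    def test_black_image_maps_to_zero(self):
        out = preprocess(np.zeros((64, 64), dtype=np.uint8), size=32)
        assert out.max() == 0.0

    def test_range_bounds(self, rng):
        out = preprocess((rng.random((100, 80)) * 255).astype(np.uint8),
                         size=48)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_idempotent_at_fixed_size(self, rng):
        first = preprocess((rng.random((60, 60)) * 255).astype(np.uint8),
                           size=32)
        second = preprocess(first[:, :, 0], size=32)
        np.testing.assert_array_equal(first, second)

    def test_channel_replication(self, rng):
        out = preprocess((rng.random((32, 32)) * 255).astype(np.uint8),
                         size=32, in_channels=3)
        assert out.shape == (32, 32, 3)
        np.testing.assert_array_equal(out[..., 0], out[..., 2])

    def test_corrupt_file_names_path(self, tmp_path):
        bad = tmp_path / "bad.png"
        bad.write_bytes(b"not a png")
        with pytest.raises(OSError, match="bad.png"):
            preprocess(bad)


class TestAugment:
    def test_null_policy_is_identity(self, rng):
        img = rng.random((32, 32, 1)).astype(np.float32)
        out = augment(img, AugmentationPolicy(0.0, 0.0, 0.0), rng)
        np.testing.assert_array_equal(out, img)

    def test_forced_mirror_twice_is_identity(self, rng):
        img = rng.random((16, 16, 1)).astype(np.float32)
        policy = AugmentationPolicy(0.0, 1.0, 0.0)
        out = augment(augment(img, policy, rng), policy, rng)
        np.testing.assert_array_equal(out, img)

    def test_reproducible_given_seed(self, mini_dataset):
        img = preprocess(mini_dataset[2].records.iloc[0]["path"], size=32)
        policy = AugmentationPolicy()
        a = augment(img, policy, np.random.default_rng(42))
        b = augment(img, policy, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            AugmentationPolicy(mirror_probability=1.5)


class TestClassWeights:
    def test_balanced_set_gives_unit_weights(self, mini_dataset):
        np.testing.assert_allclose(class_weights(mini_dataset[2]), np.ones(4))

    def test_inverse_frequency_hand_value(self, tmp_path):
        for cls, n in (("A", 30), ("B", 10)):
            d = tmp_path / "train" / cls
            d.mkdir(parents=True)
            for i in range(n):
                Image.new("L", (4, 4)).save(d / f"{i}.png")
        w = class_weights(load_image_folder(tmp_path))
        np.testing.assert_allclose(w, [0.5, 1.5])

    def test_invariant_to_duplicating_dataset(self, tmp_path):
        for cls, n in (("A", 6), ("B", 2)):
            d = tmp_path / "train" / cls
            d.mkdir(parents=True)
            for i in range(n):
                Image.new("L", (4, 4)).save(d / f"{i}.png")
        w1 = class_weights(load_image_folder(tmp_path))
        for cls, n in (("A", 6), ("B", 2)):
            d = tmp_path / "train" / cls
            for i in range(n):
                Image.new("L", (4, 4)).save(d / f"dup_{i}.png")
        w2 = class_weights(load_image_folder(tmp_path))
        np.testing.assert_allclose(w1, w2)
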