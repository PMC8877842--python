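"""Palette decoding, one-hot encoding, dataset split, augmentation and I/O."""

import numpy as np
import pytest

import sssnet as s


class TestPalette:
    def test_render_decode_round_trip(self, rng):
        lm = rng.integers(0, 5, (32, 32))
        rgb = s.DEFAULT_PALETTE.render(lm)
        assert np.array_equal(s.decode_gt(rgb, tolerance=0), lm)

    def test_decode_tolerates_intensity_jitter(self, rng):
        lm = rng.integers(0, 5, (16, 16))
        rgb = s.DEFAULT_PALETTE.render(lm).astype(np.int16)
        rgb += rng.integers(-3, 4, rgb.shape)
        rgb = np.clip(rgb, 0, 255).astype(np.uint8)
        assert np.array_equal(s.decode_gt(rgb, tolerance=10), lm)

    def test_off_palette_color_raises_with_coordinates(self):
        rgb = s.DEFAULT_PALETTE.render(np.zeros((4, 4), dtype=int))
        rgb[2, 3] = (120, 130, 140)
        with pytest.raises(ValueError, match=r"row=2, col=3"):
            s.decode_gt(rgb, tolerance=0)

    def test_duplicate_colors_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            s.Palette(names=("a", "b"), colors=((0, 0, 0), (0, 0, 0)))


class TestOneHot:
    def test_all_background(self):
        stack = s.encode_onehot(np.zeros((4, 4), dtype=int))
        assert stack.shape == (4, 4, 5)
        assert np.all(stack[..., 0] == 1) and np.all(stack[..., 1:] == 0)

    def test_round_trip_on_random_maps(self, rng):
        for _ in range(100):
            lm = rng.integers(0, 5, (8, 8))
            assert np.array_equal(s.decode_onehot(s.encode_onehot(lm)), lm)

    def test_channel_sums_match_confusion_tallies(self, rng):
        lm = rng.integers(0, 5, (16, 16))
        stack = s.encode_onehot(lm)
        counts = s.confusion_counts(lm, lm)
        assert np.array_equal(stack.sum(axis=(0, 1)), counts.tp)

    def test_non_onehot_decode_warns_and_breaks_ties_low(self):
        stack = np.zeros((1, 1, 5), dtype=np.uint8)
        stack[0, 0, [0, 2]] = 1   # tie between classes 0 and 2
        with pytest.warns(UserWarning, match="not one-hot"):
            lm = s.decode_onehot(stack)
        assert lm[0, 0] == 0
        with pytest.raises(ValueError, match="one-hot"):
            s.decode_onehot(stack, strict=True)


class TestSplit:
    def test_reference_protocol_235_gives_200_35(self):
        train, test = s.split_dataset(s.SplitSpec(n_total=235,
                                                  train_fraction=0.85,
                                                  seed=0))
        assert len(train) == 200 and len(test) == 35

    def test_rounding_small_n(self):
        train, test = s.split_dataset(s.SplitSpec(20, 0.85, seed=1))
        assert len(train) == 17 and len(test) == 3

    def test_partition_and_determinism(self):
        spec = s.SplitSpec(50, 0.8, seed=7)
        tr1, te1 = s.split_dataset(spec)
        tr2, te2 = s.split_dataset(spec)
        assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)
        assert set(tr1) | set(te1) == set(range(50))
        assert set(tr1) & set(te1) == set()

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            s.SplitSpec(0, 0.85)


class TestAugmentation:
    def test_sixteen_transforms_per_pair(self, tiny_dataset):
        phantoms, _ = tiny_dataset
        pairs = [(p.image, p.gt) for p in phantoms[:3]]
        out = s.augment(pairs)
        assert len(out) == 48

    def test_plan_must_have_sixteen(self):
        plan = s.default_augmentation_plan()
        assert len(plan.transforms) == 16
        with pytest.raises(ValueError, match="16"):
            s.AugmentationPlan(plan.transforms[:5])

    def test_horizontal_flip_is_involution(self, tiny_dataset):
        phantoms, _ = tiny_dataset
        img, lm = phantoms[0].image, phantoms[0].gt
        t = s.PairTransform("flip", flip_axis=1)
        assert np.array_equal(t.apply_image(t.apply_image(img)), img)
        assert np.array_equal(t.apply_labelmap(t.apply_labelmap(lm)), lm)

    def test_flips_and_quarter_rotations_conserve_class_counts(self,
                                                               tiny_dataset):
        phantoms, _ = tiny_dataset
        lm = phantoms[1].gt
        base = np.bincount(lm.ravel(), minlength=5)
        for t in [s.PairTransform("flip", flip_axis=0),
                  s.PairTransform("flip", flip_axis=1),
                  s.PairTransform("flip", flip_axis=2),
                  s.PairTransform("rotate", angle=90.0),
                  s.PairTransform("rotate", angle=180.0)]:
            got = np.bincount(t.apply_labelmap(lm).ravel(), minlength=5)
            assert np.array_equal(got, base), t

    def test_no_new_labels_introduced(self, tiny_dataset):
        phantoms, _ = tiny_dataset
        lm = phantoms[2].gt
        source = set(np.unique(lm)) | {0}   # 0 is the border-fill class
        for img, out in s.augment([(phantoms[2].image, lm)]):
            assert set(np.unique(out)) <= source

    def test_same_geometry_applied_to_image_and_gt(self, tiny_dataset):
        # translating the GT-rendered image must equal rendering the
        # translated GT (nearest-neighbour on a palette image is exact)
        phantoms, _ = tiny_dataset
        lm = phantoms[0].gt
        rgb = s.DEFAULT_PALETTE.render(lm)
        t = s.PairTransform("translate", shift=(7, -4))
        moved_lm = t.apply_labelmap(lm)
        # ignore border-exposed pixels (image uses edge fill, GT background)
        inner = np.zeros_like(lm, dtype=bool)
        inner[7:, :-4] = True
        rendered = s.DEFAULT_PALETTE.render(moved_lm)
        assert np.array_equal(t.apply_image(rgb)[inner], rendered[inner])

    def test_mismatched_dims_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            s.augment([(np.zeros((8, 8, 3), np.uint8),
                        np.zeros((8, 9), int))])


class TestIO:
    def test_labelmap_png_round_trip(self, rng, tmp_path):
        lm = rng.integers(0, 5, (16, 16))
        path = tmp_path / "lm.png"
        s.write_labelmap(lm, path)
        assert np.array_equal(s.read_labelmap(path), lm)

    def test_rgb_image_round_trip(self, rng, tmp_path):
        img = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        path = tmp_path / "img.png"
        s.write_image(img, path)
        assert np.array_equal(s.read_image(path), img)

    def test_sixteen_bit_input_is_rescaled(self, tmp_path):
        from PIL import Image
        arr = np.full((4, 4), 65535, dtype=np.uint16)
        path = tmp_path / "deep.png"
        Image.fromarray(arr).save(path)
        out = s.read_image(path)
        assert out.dtype == np.uint8 and np.all(out == 255)

    def test_unknown_extension_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="extension"):
            s.read_image(tmp_path / "x.tiff")

    def test_truncated_file_raises(self, tmp_path):
        path = tmp_path / "broken.png"
        path.write_bytes(b"\x89PNG\r\n\x1a\n truncated")
        with pytest.raises(Exception):
            s.read_image(path)

    def test_manifest_round_trip(self, tmp_path):
        rows = [{"image": "a.png", "label": "b.png", "split": "train"}]
        path = tmp_path / "manifest.csv"
        s.write_manifest(rows, path)
        assert s.read_manifest(path) == rows
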