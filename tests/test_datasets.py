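"""Patch extraction, augmentation, balancing and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triseg.datasets import (
    AugmentationPlan,
    Patch,
    SplitConfig,
    assemble_real_augmented_set,
    balance_sets,
    computed_augment,
    extract_patches,
    normalize_dynamic_range,
    split_dataset,
)


def toy_patch(seed=0, size=16, source="t0") -> Patch:
    rng = np.random.default_rng(seed)
    return Patch(
        image=rng.uniform(0, 1, (size, size, 1)),
        classes=rng.integers(0, 3, (size, size)),
        weights=np.ones((size, size)),
        source_id=source,
    )


class TestNormalize:
    def test_affine_closed_form(self):
        img = np.array([[100.0, 600.0, 1100.0]] * 3)
        np.testing.assert_allclose(
            normalize_dynamic_range(img), (img - 100.0) / 1000.0
        )

    def test_constant_maps_to_zero(self):
        assert np.all(normalize_dynamic_range(np.full((4, 4), 9.0)) == 0.0)

    def test_unit_range_fixed_point(self):
        img = np.array([[0.0, 0.25], [0.75, 1.0]])
        np.testing.assert_array_equal(normalize_dynamic_range(img), img)


class TestExtractPatches:
    def test_256_to_16_patches(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (256, 256))
        cls = np.zeros((256, 256), np.int64)
        w = np.ones((256, 256))
        patches = extract_patches(img, cls, w, size_px=64)
        assert len(patches) == 16

    def test_exact_fit_single_patch(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (64, 64))
        patches = extract_patches(img, np.zeros((64, 64), int), np.ones((64, 64)), 64)
        assert len(patches) == 1
        np.testing.assert_array_equal(patches[0].image[:, :, 0], img)

    def test_stride_window_arithmetic(self):
        img = np.zeros((100, 100))
        patches = extract_patches(img, np.zeros((100, 100), int), np.ones((100, 100)), 64, 32)
        assert len(patches) == 4
        assert {p.offset for p in patches} == {(0, 0), (0, 32), (32, 0), (32, 32)}

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((32, 32)), np.zeros((32, 32), int), np.ones((32, 32)), 64)


class TestComputedAugment:
    def test_rotation_preserves_class_counts(self):
        p = toy_patch()
        plan = AugmentationPlan(rotations=(90,), reflections=False, upscale_factor=1.0)
        out = computed_augment([p], plan)
        assert len(out) == 2
        for q in out:
            np.testing.assert_array_equal(
                np.bincount(q.classes.ravel(), minlength=3),
                np.bincount(p.classes.ravel(), minlength=3),
            )

    def test_upscale_keeps_patch_geometry(self):
        p = toy_patch(size=64)
        plan = AugmentationPlan(rotations=(), reflections=False, upscale_factor=1.2)
        out = computed_augment([p], plan)
        up = [q for q in out if "upscaled" in q.provenance]
        assert len(up) == 1
        assert up[0].image.shape == (64, 64, 1)
        assert up[0].classes.shape == (64, 64)

    def test_sigma_zero_blur_is_identity(self):
        p = toy_patch()
        plan = AugmentationPlan(
            rotations=(), reflections=False, upscale_factor=1.0,
            gaussian_sigmas_px=(0.0,),
        )
        out = computed_augment([p], plan)
        np.testing.assert_array_equal(out[1].image, p.image)

    def test_geometry_preserved_across_plan(self):
        p = toy_patch(size=32)
        out = computed_augment([p], AugmentationPlan(gaussian_sigmas_px=(1.0,)))
        assert all(q.image.shape == (32, 32, 1) for q in out)


class TestRealAugmentedAssembly:
    def test_no_real_equals_infocus_set(self, dense_specimen):
        out = assemble_real_augmented_set([dense_specimen], real=())
        assert len(out) == 1
        assert out[0].provenance == "infocus"

    def test_three_variants_share_identical_targets(self, dense_specimen):
        out = assemble_real_augmented_set(
            [dense_specimen], real=("defocus_plus", "defocus_minus"),
            patch_size_px=64,
        )
        assert len(out) == 12  # 4 patches x 3 variants
        by_offset = {}
        for p in out:
            by_offset.setdefault(p.offset, []).append(p)
        for variants in by_offset.values():
            assert len(variants) == 3
            for v in variants[1:]:
                np.testing.assert_array_equal(v.classes, variants[0].classes)
                np.testing.assert_array_equal(v.weights, variants[0].weights)

    def test_saturated_provenance(self, dense_specimen):
        out = assemble_real_augmented_set([dense_specimen], real=("saturated",))
        assert {p.provenance for p in out} == {"infocus", "saturated"}

    def test_missing_channel_named(self, dense_specimen):
        import copy

        spec = copy.copy(dense_specimen)
        spec.channels = {k: v for k, v in spec.channels.items() if k != "dna_plus_z"}
        with pytest.raises(ValueError, match="dna_plus_z"):
            assemble_real_augmented_set([spec], real=("defocus_plus",))

    def test_nes_second_channel(self, dense_specimen):
        out = assemble_real_augmented_set([dense_specimen], channels=("dna", "nes"))
        assert out[0].image.shape[2] == 2


class TestBalance:
    def test_equal_sizes_unchanged(self):
        a = [toy_patch(i) for i in range(3)]
        b = [toy_patch(10 + i) for i in range(3)]
        a2, b2 = balance_sets(a, b)
        assert a2 == a and b2 == b

    def test_padding_with_rotations(self):
        a = [toy_patch(i) for i in range(10)]
        b = [toy_patch(100 + i) for i in range(30)]
        a2, b2 = balance_sets(a, b, seed=1)
        assert len(a2) == len(b2) == 30
        assert a2[:10] == a  # originals never discarded
        assert all("rot" in p.provenance for p in a2[10:])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            balance_sets([], [toy_patch(0)])


class TestSplit:
    def test_default_ratios_100(self):
        items = [toy_patch(i, source=f"t{i}") for i in range(100)]
        tr, va, te = split_dataset(items, SplitConfig(seed=0))
        assert (len(tr), len(va), len(te)) == (36, 24, 40)

    def test_deterministic(self):
        items = [toy_patch(i, source=f"t{i}") for i in range(20)]
        s1 = split_dataset(items, SplitConfig(seed=5))
        s2 = split_dataset(items, SplitConfig(seed=5))
        for a, b in zip(s1, s2):
            assert [p.source_id for p in a] == [p.source_id for p in b]

    def test_five_tiles_largest_remainder(self):
        items = [toy_patch(i, source=f"t{i}") for i in range(5)]
        tr, va, te = split_dataset(items, SplitConfig(seed=0))
        assert (len(tr), len(va), len(te)) == (2, 1, 2)

    def test_tile_variants_stay_together(self):
        items = []
        for t in range(6):
            for prov in ("infocus", "defocus_plus"):
                p = toy_patch(t, source=f"tile{t}")
                p.provenance = prov
                items.append(p)
        tr, va, te = split_dataset(items, SplitConfig(seed=3))
        for part in (tr, va, te):
            sources = {p.source_id for p in part}
            # both variants of a tile land in the same part
            assert len(part) == 2 * len(sources)

    @given(n=st.integers(3, 60), seed=st.integers(0, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_disjoint_exhaustive(self, n, seed):
        items = [toy_patch(i, source=f"t{i}") for i in range(n)]
        parts = split_dataset(items, SplitConfig(seed=seed))
        ids = [p.source_id for part in parts for p in part]
        assert sorted(ids) == sorted(p.source_id for p in items)
        assert sum(len(p) for p in parts) == n
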