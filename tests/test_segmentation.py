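import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoradial import (
    ComponentSet,
    ImageStack,
    SegmentationConfig,
    binarize_stack,
    component_stats,
    filter_components,
    label_components_3d,
    make_phantom_cell,
    preprocess_stack,
    segment_stack,
)

from oracles import flood_fill_components


def make_component_set(sizes, shape=(200, 600, 600)):
    """Fabricate disjoint line-shaped components with prescribed sizes."""
    comps = []
    for i, size in enumerate(sizes):
        y = i * 2
        comps.append(np.array([(z // shape[2], y, z % shape[2]) for z in range(size)]))
    return ComponentSet(components=comps, shape=shape)


class TestPreprocess:
    def test_constant_stack_unchanged(self):
        stack = ImageStack(np.full((4, 20, 20), 500.0))
        out = preprocess_stack(stack, SegmentationConfig())
        np.testing.assert_allclose(out.data, 500.0)

    def test_slice_wise_only(self):
        data = np.zeros((5, 31, 31))
        data[2, 15, 15] = 1000.0
        out = preprocess_stack(ImageStack(data), SegmentationConfig())
        assert out.data[2].sum() > 0
        for z in (0, 1, 3, 4):
            np.testing.assert_array_equal(out.data[z], 0.0)

    def test_sharpening_steepens_step_edge(self):
        data = np.zeros((1, 40, 40))
        data[:, :, :20] = 2000.0
        cfg = SegmentationConfig()
        smoothed = preprocess_stack(ImageStack(data), cfg.replace(laplacian_weight=0.0))
        sharpened = preprocess_stack(ImageStack(data), cfg)
        grad_s = np.abs(np.diff(smoothed.data[0, 20])).max()
        grad_l = np.abs(np.diff(sharpened.data[0, 20])).max()
        assert grad_l > grad_s

    def test_output_clipped_nonnegative_and_same_shape(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 300, (3, 24, 24))
        out = preprocess_stack(ImageStack(data), SegmentationConfig())
        assert out.data.shape == data.shape
        assert out.data.min() >= 0

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            SegmentationConfig(gaussian_sigma=0.0)


class TestBinarize:
    def test_all_zero(self):
        assert not binarize_stack(ImageStack(np.zeros((2, 5, 5))), 750).any()

    def test_threshold_is_strict(self):
        data = np.zeros((1, 3, 3))
        data[0, 1, 1] = 750.0
        data[0, 0, 0] = 750.1
        mask = binarize_stack(ImageStack(data), 750)
        assert not mask[0, 1, 1]
        assert mask[0, 0, 0]

    def test_noise_free_phantom_mask_matches_truth(self, small_spec, clean_seg_config):
        stack, truth = make_phantom_cell(small_spec)
        pre = preprocess_stack(stack, clean_seg_config)
        mask = binarize_stack(pre, clean_seg_config.threshold)
        got = set(map(tuple, np.argwhere(mask).tolist()))
        assert got == truth.voxel_union()

    @given(st.floats(min_value=0, max_value=3000), st.floats(min_value=0, max_value=3000))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, t1, t2):
        rng = np.random.default_rng(17)
        stack = ImageStack(rng.uniform(0, 3000, (2, 8, 8)))
        lo, hi = sorted((t1, t2))
        assert binarize_stack(stack, hi).sum() <= binarize_stack(stack, lo).sum()


class TestLabelComponents:
    def test_diagonal_voxels_connect(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert len(label_components_3d(mask)) == 1

    def test_gap_of_two_disconnects(self):
        mask = np.zeros((3, 3, 5), dtype=bool)
        mask[0, 0, 0] = mask[0, 0, 2] = True
        assert len(label_components_3d(mask)) == 2

    def test_components_partition_mask(self):
        rng = np.random.default_rng(3)
        mask = rng.random((6, 15, 15)) < 0.2
        cs = label_components_3d(mask)
        assert sum(cs.sizes) == int(mask.sum())
        assert cs.voxel_union() == set(map(tuple, np.argwhere(mask).tolist()))

    @pytest.mark.parametrize("density", [0.05, 0.2, 0.5])
    def test_agrees_with_flood_fill_oracle(self, density):
        rng = np.random.default_rng(int(density * 100))
        for _ in range(10):
            mask = rng.random((5, 20, 20)) < density
            ours = {frozenset(map(tuple, c.tolist())) for c in label_components_3d(mask).components}
            oracle = set(flood_fill_components(mask))
            assert ours == oracle


class TestFilterComponents:
    def test_paper_size_bounds_are_inclusive_removal(self):
        cs = make_component_set([125, 126, 99_999, 100_000])
        kept = filter_components(cs, 125, 100_000)
        assert sorted(kept.sizes.tolist()) == [126, 99_999]

    def test_empty_in_empty_out(self):
        cs = ComponentSet(components=[], shape=(2, 2, 2))
        assert len(filter_components(cs)) == 0

    def test_all_singletons_removed(self):
        cs = make_component_set([1] * 5)
        assert len(filter_components(cs)) == 0

    def test_idempotent(self):
        cs = make_component_set([10, 200, 130, 99_999, 100_001])
        once = filter_components(cs)
        twice = filter_components(once)
        assert [c.shape for c in once.components] == [c.shape for c in twice.components]

    def test_order_preserved(self):
        cs = make_component_set([300, 1, 200, 400])
        assert filter_components(cs).sizes.tolist() == [300, 200, 400]

    @given(st.lists(st.integers(min_value=1, max_value=300), max_size=8))
    @settings(max_examples=30, deadline=None)
    def test_survivors_within_bounds(self, sizes):
        kept = filter_components(make_component_set(sizes), 20, 250)
        assert all(20 < s < 250 for s in kept.sizes)


class TestComponentStats:
    def test_mean_of_two(self):
        stats = component_stats(make_component_set([200, 400]))
        assert stats.n_components == 2
        assert stats.mean_component_size == 300

    def test_empty_reports_missing_mean(self):
        stats = component_stats(ComponentSet(components=[], shape=(1, 1, 1)))
        assert stats.n_components == 0
        assert stats.mean_component_size is None

    def test_phantom_component_count_matches_truth(self, small_spec, clean_seg_config):
        stack, truth = make_phantom_cell(small_spec)
        cs = segment_stack(stack, clean_seg_config)
        assert component_stats(cs).n_components == len(truth.mito_voxels)


class TestEndToEnd:
    def test_noise_free_recovery_exact(self, small_spec, clean_seg_config):
        stack, truth = make_phantom_cell(small_spec)
        cs = segment_stack(stack, clean_seg_config)
        assert cs.voxel_union() == truth.voxel_union()

    def test_default_sigma_recovers_counts_and_most_voxels(self, small_spec):
        stack, truth = make_phantom_cell(small_spec)
        cs = segment_stack(stack, SegmentationConfig(min_size_excl=0))
        assert len(cs) == len(truth.mito_voxels)
        union, tset = cs.voxel_union(), truth.voxel_union()
        iou = len(union & tset) / len(union | tset)
        assert iou > 0.6
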