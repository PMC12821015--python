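import numpy as np
import pytest

from mitoradial import PhantomSpec, SegmentationConfig


@pytest.fixture
def small_spec() -> PhantomSpec:
    """A quick-to-render cell: 9 slices, 160x160, a dozen mitochondria."""
    return PhantomSpec(
        stack_shape=(9, 160, 160),
        cell_radius=3.5,
        nucleus_radius=0.8,
        n_mito=12,
        mito_length_range=(0.5, 1.0),
        mito_radius=0.15,
        z_extent=0.3,
        seed=7,
    )


@pytest.fixture
def clean_seg_config() -> SegmentationConfig:
    """Light smoothing for noise-free phantoms; keeps tiny components."""
    return SegmentationConfig(gaussian_sigma=0.5, min_size_excl=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def speckle_spec(**overrides) -> PhantomSpec:
    """Many near-voxel-sized mitochondria: pooled pixels are approximately
    independent draws from the radial law, so pixel-count KS statistics
    behave nominally. Used for distribution-level pipeline checks."""
    kwargs = dict(
        stack_shape=(5, 128, 128),
        cell_radius=3.0,
        nucleus_radius=0.35,
        n_mito=100,
        mito_length_range=(0.02, 0.06),
        mito_radius=0.045,
        z_extent=0.08,
        min_separation=0.05,
        nucleus_center=(2.0, 64.0, 64.0),
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def speckle_seg_config(**overrides) -> SegmentationConfig:
    kwargs = dict(gaussian_sigma=0.6, min_size_excl=0)
    kwargs.update(overrides)
    return SegmentationConfig(**kwargs)


def ks_distance_to_r_squared(radii: np.ndarray) -> float:
    """sup |ECDF(r) - r^2| against the uniform-disk radial law."""
    r = np.sort(np.asarray(radii, dtype=float))
    n = r.size
    cdf = np.clip(r, 0.0, 1.0) ** 2
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(np.maximum(np.abs(ecdf_hi - cdf), np.abs(ecdf_lo - cdf)).max())
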