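"""Normalized radial distance distributions and condition comparison.

Every segmented mitochondrial voxel contributes one distance to the
nucleus centre; distances are normalized per cell by the cell's maximum
mitochondrial-voxel distance, pooled across the cells of a condition
(pixel-weighted), optionally restricted to the most peripheral fraction,
and compared between conditions with a two-sample Kolmogorov-Smirnov test.

Note: pooling pixels across cells means KS sample sizes are pixel counts,
ignoring within-cell and within-mitochondrion correlation. That convention
is preserved deliberately; treat p-values on clustered pixel data as
descriptive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .segmentation import ComponentSet

__all__ = [
    "NormalizedDistanceSet",
    "RadialHistogram",
    "KSResult",
    "compute_pixel_distances",
    "normalize_distances",
    "pool_condition",
    "peripheral_subset",
    "ks_two_sample",
    "radial_histogram",
]

#: use the exact small-sample KS null distribution when n*m is at most this
EXACT_KS_LIMIT = 10_000


@dataclass
class NormalizedDistanceSet:
    """Per-cell normalized radial distances, each in [0, 1] with max 1."""

    cell_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class RadialHistogram:
    """Density-normalized histogram over [0, 1]."""

    bin_edges: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.bin_edges.size != self.densities.size + 1:
            raise ValueError("need len(bin_edges) == len(densities) + 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)


@dataclass(frozen=True)
class KSResult:
    """Two-sample KS comparison: D in [0, 1], p in (0, 1]."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str


def compute_pixel_distances(
    cs: ComponentSet,
    nucleus_center: Sequence[float],
    voxel_size: Sequence[float],
    distance_units: str = "physical",
    allow_center_outside: bool = False,
) -> np.ndarray:
    """Euclidean distance of every component voxel to the nucleus centre.

    ``nucleus_center`` is in ``(z, y, x)`` voxel coordinates (fractional
    allowed) and ``voxel_size`` in ``(dz, dy, dx)`` micrometres. With
    ``distance_units="physical"`` (default) each axis offset is scaled by
    its voxel dimension before taking the norm; ``"voxel"`` uses raw index
    offsets (incommensurate axes, kept for parity with index-space
    conventions).
    """
    center = np.asarray(nucleus_center, dtype=float)
    if center.shape != (3,):
        raise ValueError("nucleus_center must be (z, y, x)")
    if np.any(center < 0) or np.any(center > np.array(cs.shape) - 1):
        if not allow_center_outside:
            raise ValueError(
                f"nucleus centre {tuple(center)} lies outside the stack bounds "
                f"{cs.shape}; pass allow_center_outside=True to override"
            )
    if distance_units == "physical":
        scale = np.asarray(voxel_size, dtype=float)
        if scale.shape != (3,) or np.any(scale <= 0):
            raise ValueError("voxel_size must be three positive dimensions (dz, dy, dx)")
    elif distance_units == "voxel":
        scale = np.ones(3)
    else:
        raise ValueError(f"distance_units must be 'physical' or 'voxel', got {distance_units!r}")
    coords = cs.voxel_coordinates().astype(float)
    return np.linalg.norm((coords - center) * scale, axis=1)


def normalize_distances(distances: np.ndarray, cell_id: str = "") -> NormalizedDistanceSet:
    """Scale distances by their maximum so the largest value is exactly 1."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError(f"cell {cell_id!r} has no mitochondrial pixels; cannot normalize")
    mx = distances.max()
    values = distances / mx if mx > 0 else np.ones_like(distances)
    return NormalizedDistanceSet(cell_id=cell_id, values=values)


def pool_condition(cells: Sequence[NormalizedDistanceSet]) -> np.ndarray:
    """Concatenate all cells' values (pixel-weighted pooling)."""
    if len(cells) == 0:
        raise ValueError("cannot pool an empty list of cells")
    return np.concatenate([c.values for c in cells])


def peripheral_subset(pooled: np.ndarray, fraction: float = 0.30) -> np.ndarray:
    """The ``ceil(fraction * n)`` largest values, ties at the cutoff kept.

    Tie handling makes the subset deterministic and independent of input
    order, at the cost of occasionally returning slightly more than the
    nominal fraction.
    """
    pooled = np.asarray(pooled, dtype=float)
    if pooled.size == 0:
        raise ValueError("cannot take the peripheral subset of an empty pool")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = math.ceil(fraction * pooled.size)
    cutoff = np.sort(pooled)[-k]
    return pooled[pooled >= cutoff]


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> KSResult:
    """Two-sided two-sample KS test.

    D is the supremum ECDF distance. The p-value uses the exact
    small-sample null distribution when ``n1 * n2 <= 10_000`` and the
    asymptotic Kolmogorov distribution otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    method = "exact" if a.size * b.size <= EXACT_KS_LIMIT else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return KSResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=int(a.size),
        n2=int(b.size),
        method=method,
    )


def radial_histogram(pooled: np.ndarray, n_bins: int = 50) -> RadialHistogram:
    """Density histogram of pooled values on equal bins over [0, 1]."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    pooled = np.asarray(pooled, dtype=float)
    densities, edges = np.histogram(pooled, bins=n_bins, range=(0.0, 1.0), density=True)
    return RadialHistogram(bin_edges=edges, densities=densities)
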