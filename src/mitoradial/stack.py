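"""Image stack container and TIFF I/O.

Stacks are stored as ``(z, y, x)`` float arrays with anisotropic physical
voxel dimensions ``(dz, dy, dx)`` in micrometres. On disk they are
multi-page 16-bit unsigned TIFFs with z-ordered pages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack"]

#: default physical voxel dimensions (dz, dy, dx) in micrometres
DEFAULT_VOXEL_SIZE = (0.2, 0.0542, 0.0542)


@dataclass
class ImageStack:
    """3D grid of nonnegative intensities with physical voxel dimensions."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x), got shape {self.data.shape}")
        if self.data.size == 0:
            raise ValueError("stack must be nonempty")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel dimensions must be positive, got {self.voxel_size}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a z-paged uint16 TIFF (values clipped to range)."""
    path = Path(path)
    data = np.clip(np.rint(stack.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def read_stack(path: str | Path, voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE) -> ImageStack:
    """Read a multi-page TIFF as a float64 stack."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data.astype(np.float64), voxel_size)
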