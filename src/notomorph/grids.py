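"""Core in-memory containers for 3D image data with physical voxel spacing.

Axis convention used throughout the package: arrays are indexed
``(ap, dv, lr)`` — anteroposterior, dorsoventral, left-right — 0-based,
with voxel centers at integer indices and physical coordinate
``index * spacing``.  AP is always axis 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid3D", "LabelVolume", "AXES"]

AXES = ("ap", "dv", "lr")


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 entries (ap, dv, lr), got {spacing}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be strictly positive, got {spacing}")
    return spacing


@dataclass
class VoxelGrid3D:
    """A raw intensity volume with voxel spacing in micrometres.

    Parameters
    ----------
    data : ndarray, shape (n_ap, n_dv, n_lr)
        Intensity values.
    spacing : tuple of float
        Physical voxel spacing ``(ap, dv, lr)`` in µm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.spacing))


@dataclass
class LabelVolume:
    """An integer-labelled instance volume; 0 is background.

    Labels need not be consecutive but are unique per instance.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    border_flags: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def ids(self) -> np.ndarray:
        """Sorted array of instance labels present (background excluded)."""
        out = np.unique(self.labels)
        return out[out != 0]

    def mask(self, label: int) -> np.ndarray:
        """Boolean mask of one instance."""
        return self.labels == label
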