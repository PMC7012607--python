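"""Per-cell shape statistics: volume, surface area, sphericity, AP profiles.

The sphericity index of a cell is the ratio of the surface area of a
sphere of equal volume to the cell's own surface area,

    Ψ = π^(1/3) (6V)^(2/3) / A,

which is 1 for a perfect sphere and decreases as the shape is distorted
(isoperimetric inequality).  Volumes are voxel counts times the physical
voxel volume; surface areas come from a watertight iso-surface mesh of
the instance mask (marching cubes followed by Taubin mesh smoothing),
because the raw staircase area of a digitized smooth object
overestimates the true area by tens of percent and would bias Ψ low,
while smoothing the *image* instead of the mesh shrinks small objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from skimage import measure

from .grids import LabelVolume

__all__ = [
    "CellShapeRecord",
    "CohortSummary",
    "measure_cell",
    "measure_all",
    "summarize_cohort",
    "profile_distance",
    "sphericity_from_v_a",
]

#: Taubin smoothing iterations applied to the marching-cubes mesh.
#: 20 iterations suppress the staircase area overestimate to <1% on
#: digitized spheres and spheroids without the shrinkage a Gaussian
#: pre-filter of the image would cause on objects a few voxels across.
TAUBIN_ITERATIONS = 20


@dataclass
class CellShapeRecord:
    """Shape measurements of one labelled instance."""

    cell_id: int
    centroid: tuple[float, float, float]  # (ap, dv, lr) µm
    volume: float          # µm³
    surface_area: float    # µm²
    sphericity: float      # dimensionless, in (0, 1] up to mesh tolerance
    ap_position: float     # µm, centroid AP coordinate
    on_border: bool = False  # instance touches the grid border (open-mesh risk)


@dataclass
class CohortSummary:
    """Cohort-level morphometrics of one specimen."""

    n_cells: int
    notochord_length: float  # µm, occupied AP extent
    mean_sphericity: float
    volume_by_ap: list[tuple[float, float]]  # AP-sorted (ap µm, volume µm³)


def sphericity_from_v_a(volume: float, area: float) -> float:
    """Sphericity Ψ = π^(1/3) (6V)^(2/3) / A (area of the equal-volume
    sphere divided by the object's area)."""
    return math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area


def _mesh_area(mask: np.ndarray, spacing) -> float:
    """Surface area (µm²) of a binary mask from a Taubin-smoothed
    marching-cubes iso-surface (watertight by construction after
    padding)."""
    field = np.pad(mask.astype(np.float32), 2)
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=spacing)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    trimesh.smoothing.filter_taubin(mesh, iterations=TAUBIN_ITERATIONS)
    return float(mesh.area)


def measure_cell(labels: LabelVolume, cell_id: int) -> CellShapeRecord:
    """Measure volume, surface area and sphericity of one instance.

    Volume is the voxel count times the voxel volume; surface area comes
    from a watertight iso-surface mesh (see module docstring).  Instances
    touching the grid border are measured anyway but flagged, since their
    mesh is closed by the border rather than by the true cell boundary.

    Raises
    ------
    KeyError
        If ``cell_id`` is not present in the volume.
    """
    sl = ndimage.find_objects((labels.labels == cell_id).astype(np.int8))
    if not sl or sl[0] is None:
        raise KeyError(f"label {cell_id} not present in the volume")
    sl = sl[0]
    mask = labels.labels[sl] == cell_id

    on_border = any(
        s.start == 0 or s.stop == dim
        for s, dim in zip(sl, labels.shape)
    )

    n_vox = int(mask.sum())
    volume = n_vox * labels.voxel_volume
    area = _mesh_area(mask, labels.spacing)

    idx = np.argwhere(mask) + [s.start for s in sl]
    centroid = tuple(float(c) for c in idx.mean(axis=0) * np.asarray(labels.spacing))

    return CellShapeRecord(
        cell_id=int(cell_id),
        centroid=centroid,
        volume=float(volume),
        surface_area=area,
        sphericity=sphericity_from_v_a(volume, area),
        ap_position=centroid[0],
        on_border=on_border,
    )


def measure_all(labels: LabelVolume) -> list[CellShapeRecord]:
    """Measure every instance in the volume, in label order."""
    return [measure_cell(labels, int(lab)) for lab in labels.ids()]


def summarize_cohort(
    records: list[CellShapeRecord], labels: LabelVolume
) -> CohortSummary:
    """Cohort summary: cell count, notochord length, mean sphericity and
    the AP-sorted volume profile.

    Notochord length is the occupied AP extent of the union of instances
    (max minus min occupied AP coordinate, physical units).  For kinked
    specimens use the centerline arc length from the kink analysis
    instead; the AP extent underestimates a bent axis.
    """
    if not records:
        raise ValueError("empty record list")
    occupied = np.flatnonzero((labels.labels > 0).any(axis=(1, 2)))
    length = float((occupied[-1] - occupied[0]) * labels.spacing[0])
    by_ap = sorted((r.ap_position, r.volume) for r in records)
    return CohortSummary(
        n_cells=len(records),
        notochord_length=length,
        mean_sphericity=float(np.mean([r.sphericity for r in records])),
        volume_by_ap=by_ap,
    )


def profile_distance(volume_by_ap_a, volume_by_ap_b, n_grid: int = 100) -> float:
    """L1 dissimilarity between two AP volume profiles.

    Both profiles are normalized in AP to [0, 1] and linearly interpolated
    to a common grid; the score is the mean absolute volume difference
    (µm³).  It is 0 iff the profiles are identical after AP normalization,
    and symmetric in its arguments.
    """
    out = []
    for prof in (volume_by_ap_a, volume_by_ap_b):
        arr = np.asarray(sorted(prof), dtype=float)
        if arr.size == 0:
            raise ValueError("empty profile")
        ap, vol = arr[:, 0], arr[:, 1]
        if ap[-1] == ap[0]:
            raise ValueError("profile has zero AP extent")
        ap_norm = (ap - ap[0]) / (ap[-1] - ap[0])
        grid = np.linspace(0.0, 1.0, n_grid)
        out.append(np.interp(grid, ap_norm, vol))
    return float(np.mean(np.abs(out[0] - out[1])))


def records_to_frame(records: list[CellShapeRecord]) -> pd.DataFrame:
    """Tabulate shape records (one row per cell, units in column names)."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "centroid_ap_um": [r.centroid[0] for r in records],
            "centroid_dv_um": [r.centroid[1] for r in records],
            "centroid_lr_um": [r.centroid[2] for r in records],
            "volume_um3": [r.volume for r in records],
            "surface_area_um2": [r.surface_area for r in records],
            "sphericity": [r.sphericity for r in records],
            "on_border": [r.on_border for r in records],
        }
    )
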