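"""TIFF and table I/O with explicit physical voxel spacing.

Volumes are written as ImageJ-style TIFF with the (ap, dv, lr) axes
mapped to (Z, Y, X) and spacing stored in the standard resolution tags
plus ImageJ metadata.  Reading requires spacing from the file metadata or
an explicit override (which always wins, with a warning); a missing
spacing is an error, never a silent 1-µm default.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grids import LabelVolume, VoxelGrid3D

__all__ = ["read_volume", "write_volume", "write_table", "read_labels"]


def write_volume(path, volume: VoxelGrid3D | LabelVolume) -> None:
    """Write a volume as ImageJ TIFF with spacing metadata.

    Label volumes are stored as 16-bit unsigned integers.
    """
    path = Path(path)
    if isinstance(volume, LabelVolume):
        data = volume.labels
        if data.max() > np.iinfo(np.uint16).max:
            raise ValueError("label ids exceed 16-bit range")
        data = data.astype(np.uint16)
    else:
        data = np.asarray(volume.data, dtype=np.float32)
    s_ap, s_dv, s_lr = volume.spacing
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        photometric="minisblack",
        resolution=(1.0 / s_lr, 1.0 / s_dv),
        metadata={"spacing": s_ap, "unit": "um", "axes": "ZYX"},
    )


def _spacing_from_tiff(tif: tifffile.TiffFile) -> tuple | None:
    try:
        page = tif.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        s_lr = xres[1] / xres[0]
        s_dv = yres[1] / yres[0]
    except (KeyError, ZeroDivisionError):
        return None
    meta = tif.imagej_metadata or {}
    s_ap = meta.get("spacing")
    if s_ap is None:
        return None
    return (float(s_ap), float(s_dv), float(s_lr))


def read_volume(path, spacing_override=None, as_labels: bool = False):
    """Read a TIFF stack with its voxel spacing.

    Parameters
    ----------
    spacing_override : tuple of 3 floats, optional
        Overrides any spacing found in the file (a warning is emitted if
        the file also carried spacing metadata).
    as_labels : bool
        Return a :class:`LabelVolume` instead of a :class:`VoxelGrid3D`.

    Raises
    ------
    ValueError
        If no spacing is available from metadata or override.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        file_spacing = _spacing_from_tiff(tif)

    if spacing_override is not None:
        if file_spacing is not None:
            warnings.warn(
                f"{path.name}: spacing override {tuple(spacing_override)} "
                f"replaces file metadata {file_spacing}"
            )
        spacing = tuple(float(s) for s in spacing_override)
    elif file_spacing is not None:
        spacing = file_spacing
    else:
        raise ValueError(
            f"{path}: no voxel spacing in TIFF metadata; pass spacing_override "
            "(a silent default would corrupt physical measurements)"
        )

    if data.ndim == 2:
        data = data[None, ...]
    if as_labels:
        return LabelVolume(data.astype(np.int32), spacing)
    return VoxelGrid3D(data, spacing)


def read_labels(path, spacing_override=None) -> LabelVolume:
    """Shorthand for :func:`read_volume` with ``as_labels=True``."""
    return read_volume(path, spacing_override=spacing_override, as_labels=True)


# column -> unit vocabulary used in sidecar schemas
_UNITS = {
    "um": "micrometre",
    "um2": "square micrometre",
    "um3": "cubic micrometre",
    "deg": "degree",
}


def write_table(frame: pd.DataFrame, path, description: str = "") -> None:
    """Write a CSV (RFC 4180, UTF-8, '.' decimal separator) plus a sidecar
    JSON schema describing each column's unit (parsed from the ``_um`` /
    ``_um2`` / ``_um3`` / ``_deg`` column-name suffixes)."""
    path = Path(path)
    frame.to_csv(path, index=False, lineterminator="\r\n", encoding="utf-8")
    columns = {}
    for col in frame.columns:
        suffix = col.rsplit("_", 1)[-1]
        columns[col] = {
            "dtype": str(frame[col].dtype),
            "unit": _UNITS.get(suffix, "dimensionless"),
        }
    schema = {"description": description, "columns": columns}
    path.with_suffix(path.suffix + ".schema.json").write_text(
        json.dumps(schema, indent=2) + "\n", encoding="utf-8"
    )
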