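"""Nuclear position and shape as read-outs of notochord internal pressure.

In a pressurised notochord the vacuole fills the cell and squeezes the
nucleus against the outer cell boundary, so nuclear centroids cluster at
the periphery of the notochord cross-section and nuclei flatten into
discs.  When vacuoles fragment and pressure drops, nuclei stay spheroid
and sit anywhere in the cross-section.  This module measures, per
nucleus, the radial fraction

    ρ = (distance of the nuclear centroid from the notochord axis)
        / (local notochord radius)

together with nuclear volume and sphericity, and tests peripherality
against the null hypothesis of uniform placement over the cross-sectional
disk, whose CDF in ρ is F(x) = x² (so E[ρ] = 2/3 under the null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import cellmorph
from .grids import LabelVolume

__all__ = [
    "NucleusRecord",
    "radial_positions",
    "peripherality_test",
    "uniform_disk_cdf",
]


@dataclass
class NucleusRecord:
    """Per-nucleus measurements."""

    nucleus_id: int
    volume: float        # µm³
    sphericity: float
    radial_fraction: float  # ρ in [0, 1]


def uniform_disk_cdf(x):
    """CDF of ρ when nuclei are uniform over the cross-sectional disk."""
    return np.square(x)


def radial_positions(
    nucleus_labels: LabelVolume,
    notochord_mask: LabelVolume,
    measure_shape: bool = True,
) -> list[NucleusRecord]:
    """Radial fraction ρ (plus volume and sphericity) for every nucleus.

    For each nucleus, ρ is computed in the notochord cross-section at the
    AP position of the nuclear centroid: the local axis is the centroid of
    that cross-section of ``notochord_mask`` (any non-zero label) and the
    local radius is the equivalent-circle radius of its area, which is
    robust to mild non-circularity.  A single-section (histology) mask
    works the same way with an AP extent of one voxel.

    Parameters
    ----------
    measure_shape : bool
        If False, skip the mesh-based volume/sphericity measurement
        (records carry NaN); useful when only positions are needed.

    Raises
    ------
    ValueError
        If a nuclear centroid falls outside the notochord mask (the id is
        named in the message), or the masks differ in shape.
    """
    if nucleus_labels.shape != notochord_mask.shape:
        raise ValueError(
            f"shape mismatch: nuclei {nucleus_labels.shape} "
            f"vs notochord {notochord_mask.shape}"
        )
    s_ap, s_dv, s_lr = nucleus_labels.spacing
    noto = notochord_mask.labels > 0

    records = []
    ids = nucleus_labels.ids()
    centroids = ndimage.center_of_mass(
        np.ones(nucleus_labels.shape), nucleus_labels.labels, ids
    )
    for nid, centroid in zip(ids, centroids):
        ap_idx = int(round(centroid[0]))
        ap_idx = min(max(ap_idx, 0), noto.shape[0] - 1)
        section = noto[ap_idx]
        if not section.any():
            raise ValueError(
                f"nucleus {nid}: no notochord cross-section at AP index {ap_idx}"
            )
        dv_idx, lr_idx = np.nonzero(section)
        center_dv = dv_idx.mean() * s_dv
        center_lr = lr_idx.mean() * s_lr
        area = len(dv_idx) * s_dv * s_lr
        local_radius = np.sqrt(area / np.pi)

        d = np.hypot(centroid[1] * s_dv - center_dv, centroid[2] * s_lr - center_lr)
        rho = d / local_radius
        voxel_diag = float(np.hypot(s_dv, s_lr))
        if rho > 1.0 + voxel_diag / local_radius:
            raise ValueError(
                f"nucleus {nid}: centroid outside the notochord mask (ρ = {rho:.3f})"
            )
        rho = min(rho, 1.0)

        if measure_shape:
            rec = cellmorph.measure_cell(nucleus_labels, int(nid))
            vol, sph = rec.volume, rec.sphericity
        else:
            vol = sph = float("nan")
        records.append(
            NucleusRecord(
                nucleus_id=int(nid),
                volume=vol,
                sphericity=sph,
                radial_fraction=float(rho),
            )
        )
    return records


def _ks_statistic_uniform_disk(rhos: np.ndarray) -> float:
    """Sup-distance between the empirical CDF of ρ and F(x) = x²."""
    x = np.sort(rhos)
    n = len(x)
    f = uniform_disk_cdf(x)
    upper = np.max(np.arange(1, n + 1) / n - f)
    lower = np.max(f - np.arange(0, n) / n)
    return float(max(upper, lower))


def peripherality_test(
    rhos, n_null: int = 9999, seed: int | None = None
) -> tuple[float, float]:
    """Kolmogorov–Smirnov-type test of ρ against the uniform-in-disk null.

    The statistic D is the sup-distance between the empirical CDF of the
    observed ρ and the null CDF F(x) = x².  The p-value comes from
    Monte-Carlo resampling: ``n_null`` same-size samples are drawn from
    the null (ρ = sqrt(U), U uniform) and p = (1 + #{D* >= D}) / (n_null
    + 1), which is exactly valid for finite ``n_null``.

    Raises
    ------
    ValueError
        For fewer than 5 observations or ρ outside [0, 1].
    """
    rhos = np.asarray(rhos, dtype=float)
    if rhos.ndim != 1 or len(rhos) < 5:
        raise ValueError("need at least 5 radial fractions")
    if np.any((rhos < 0) | (rhos > 1)):
        raise ValueError("radial fractions must lie in [0, 1]")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")

    d_obs = _ks_statistic_uniform_disk(rhos)

    rng = np.random.default_rng(seed)
    n = len(rhos)
    draws = np.sqrt(rng.random((n_null, n)))
    draws.sort(axis=1)
    f = uniform_disk_cdf(draws)
    upper = (np.arange(1, n + 1) / n - f).max(axis=1)
    lower = (f - np.arange(0, n) / n).max(axis=1)
    d_null = np.maximum(upper, lower)

    p = (1 + int(np.sum(d_null >= d_obs))) / (n_null + 1)
    return d_obs, float(p)


def records_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nucleus_id": [r.nucleus_id for r in records],
            "volume_um3": [r.volume for r in records],
            "sphericity": [r.sphericity for r in records],
            "radial_fraction": [r.radial_fraction for r in records],
        }
    )
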