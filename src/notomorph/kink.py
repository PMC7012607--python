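"""Spine/notochord centerline extraction, kink angles, kink detection, and
kink–asymmetry-flip colocalization.

A kink is a localized bend of the axis.  Its magnitude is the interior
angle between two total-least-squares lines fitted to the centerline in a
window on either side of the position: 180° means locally straight, and
the angle decreases as the kink sharpens.  Positions along the centerline
are arc-length positions (equal to the AP coordinate for a straight
axis), which makes every measurement invariant to rigid rotation and
translation of the specimen.

The colocalization test asks whether kinks sit near places where the
dorsoventral asymmetry of the per-centrum notochord deformation flips
sign.  Distances are counted in centrum units, which makes the
permutation null (kinks re-placed uniformly among inter-centrum
boundaries) exchangeable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .deform import CentrumDeformation

__all__ = [
    "Centerline",
    "KinkRecord",
    "extract_centerline",
    "kink_angle",
    "detect_kinks",
    "flip_colocalization",
]


@dataclass
class Centerline:
    """Ordered centerline points (ap, dv[, lr]) in µm."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] not in (2, 3):
            raise ValueError("centerline points must be (N, 2) or (N, 3)")
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive centerline points must be distinct")
        self._cumlen = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def arc_length(self) -> float:
        """Total arc length in µm."""
        return float(self._cumlen[-1])

    @property
    def cumulative_length(self) -> np.ndarray:
        return self._cumlen

    def point_at(self, s: float) -> np.ndarray:
        """Point at arc-length position ``s`` (linear interpolation)."""
        s = float(np.clip(s, 0.0, self.arc_length))
        out = np.empty(self.points.shape[1])
        for d in range(self.points.shape[1]):
            out[d] = np.interp(s, self._cumlen, self.points[:, d])
        return out


@dataclass
class KinkRecord:
    """A detected kink: arc-length position, interior angle, bending plane."""

    ap_position: float      # µm along the centerline
    interior_angle: float   # degrees, < 180
    plane: str              # dorsoventral | leftright | mixed


def extract_centerline(
    mask: np.ndarray, spacing, smooth_window: int = 5
) -> Centerline:
    """Centerline of an elongated binary region from per-AP-slice
    centroids, lightly smoothed.

    Parameters
    ----------
    mask : 2D or 3D boolean array, indexed (ap, dv[, lr]).
    spacing : physical voxel spacing, same length as ``mask.ndim``.
    smooth_window : odd moving-average window (in AP slices).

    Raises
    ------
    ValueError
        If the mask is empty or has more than one connected component
        (the component count is reported).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim not in (2, 3):
        raise ValueError("mask must be 2D or 3D")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (mask.ndim,):
        raise ValueError("spacing must match mask dimensionality")
    if not mask.any():
        raise ValueError("mask is empty")
    _, n_comp = ndimage.label(mask, structure=np.ones((3,) * mask.ndim))
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} connected components, expected 1")

    ap_slices = np.flatnonzero(mask.any(axis=tuple(range(1, mask.ndim))))
    pts = []
    for i in ap_slices:
        idx = np.argwhere(mask[i])
        centroid = idx.mean(axis=0)
        pts.append([i, *centroid])
    pts = np.asarray(pts, dtype=float) * spacing

    if smooth_window > 1 and len(pts) > smooth_window:
        w = smooth_window | 1  # force odd
        kernel = np.ones(w) / w
        for d in range(1, pts.shape[1]):
            # reflect-pad so the endpoints are not pulled inward
            padded = np.pad(pts[:, d], w // 2, mode="reflect")
            pts[:, d] = np.convolve(padded, kernel, mode="valid")
    return Centerline(points=pts)


def _segment_direction(centerline: Centerline, s0: float, s1: float,
                       n_samples: int = 16) -> np.ndarray:
    """Total-least-squares direction of the centerline between arc
    positions s0 < s1, oriented along increasing arc length."""
    s = np.linspace(s0, s1, n_samples)
    pts = np.array([centerline.point_at(si) for si in s])
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    chord = pts[-1] - pts[0]
    if direction @ chord < 0:
        direction = -direction
    norm = np.linalg.norm(direction)
    return direction / norm


def kink_angle(centerline: Centerline, position: float, window: float) -> float:
    """Interior angle (degrees) of the centerline at an arc-length
    position.

    Two total-least-squares lines are fitted to the centerline over
    ``[position - window, position]`` and ``[position, position +
    window]``; the interior angle between them is 180° minus the angle
    between their (arc-oriented) directions, so a straight centerline
    scores exactly 180°.  Invariant under rigid rotation, translation and
    reversal of orientation.

    Raises
    ------
    ValueError
        If the window does not fit within the centerline on both sides.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    total = centerline.arc_length
    if position - window < -1e-9 or position + window > total + 1e-9:
        raise ValueError(
            f"window {window} µm does not fit at position {position} µm "
            f"(centerline arc length {total:.1f} µm)"
        )
    d1 = _segment_direction(centerline, position - window, position)
    d2 = _segment_direction(centerline, position, position + window)
    cos_dev = float(np.clip(d1 @ d2, -1.0, 1.0))
    return 180.0 - math.degrees(math.acos(cos_dev))


def _bending_plane(centerline: Centerline, position: float, window: float) -> str:
    """Dominant bending plane at a kink (3D only; 2D is dorsoventral)."""
    if centerline.points.shape[1] == 2:
        return "dorsoventral"
    d1 = _segment_direction(centerline, position - window, position)
    d2 = _segment_direction(centerline, position, position + window)
    turn = d2 - d1
    dv, lr = abs(turn[1]), abs(turn[2])
    if dv >= 2 * lr:
        return "dorsoventral"
    if lr >= 2 * dv:
        return "leftright"
    return "mixed"


def detect_kinks(
    centerline: Centerline,
    window: float = 150.0,
    threshold_deg: float = 160.0,
    step: float | None = None,
) -> list[KinkRecord]:
    """Detect kinks as local minima of the sliding kink-angle profile.

    Positions with interior angle below ``threshold_deg`` are candidate
    kinks; candidates are non-maximum-suppressed within one window (the
    sharpest survives) and returned sorted by position.

    Raises
    ------
    ValueError
        If the centerline is shorter than twice the window.
    """
    total = centerline.arc_length
    if total <= 2 * window:
        raise ValueError(
            f"centerline arc length {total:.1f} µm must exceed twice the "
            f"window ({2 * window:.1f} µm)"
        )
    if step is None:
        step = window / 20.0
    positions = np.arange(window, total - window + step / 2, step)
    positions = positions[positions <= total - window]
    angles = np.array([kink_angle(centerline, p, window) for p in positions])

    candidates = []
    for i, (pos, ang) in enumerate(zip(positions, angles)):
        if ang >= threshold_deg:
            continue
        left = angles[i - 1] if i > 0 else np.inf
        right = angles[i + 1] if i < len(angles) - 1 else np.inf
        if ang <= left and ang <= right:
            candidates.append((ang, pos))

    candidates.sort()  # sharpest first
    accepted: list[tuple[float, float]] = []
    for ang, pos in candidates:
        if all(abs(pos - p) > window for _, p in accepted):
            accepted.append((ang, pos))

    records = [
        KinkRecord(
            ap_position=float(pos),
            interior_angle=float(ang),
            plane=_bending_plane(centerline, pos, window),
        )
        for ang, pos in accepted
    ]
    records.sort(key=lambda r: r.ap_position)
    return records


def flip_colocalization(
    deformations: list[CentrumDeformation],
    kinks: list[KinkRecord],
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test for colocalization of kinks with flips in the
    orientation of the per-centrum deformation asymmetry.

    A *flip* is a sign change of ``signed_asymmetry`` between consecutive
    centra; a flip and each kink are assigned to the nearest inter-centrum
    boundary (index i lies between centrum i and i+1).  The observed
    statistic is the mean distance, in centrum counts, from each kink to
    its nearest flip.  The null re-places the kinks independently and
    uniformly among the inter-centrum boundaries (``n_perm`` draws);
    p = (1 + #{null mean <= observed}) / (n_perm + 1).

    Returns
    -------
    (mean_distance, p_value)
        ``mean_distance = inf`` and p = 1.0 (with a warning) when no flips
        are present.
    """
    if len(deformations) < 2:
        raise ValueError("need at least 2 centra")
    if not kinks:
        raise ValueError("need at least 1 kink")
    deformations = sorted(deformations, key=lambda d: d.centrum_index)

    asym = np.array([d.signed_asymmetry for d in deformations])
    signs = np.sign(asym)
    flips = np.flatnonzero(signs[:-1] * signs[1:] < 0)
    n_boundaries = len(deformations) - 1

    # boundary AP positions from the recorded centrum spans
    bounds_ap = np.array(
        [
            0.5 * (deformations[i].ap_end + deformations[i + 1].ap_start)
            for i in range(n_boundaries)
        ]
    )
    if np.any(~np.isfinite(bounds_ap)):
        raise ValueError(
            "deformations carry no centrum spans (ap_start/ap_end); "
            "compute them with deformation_index on a profile with centra"
        )
    kink_bounds = np.array(
        [int(np.argmin(np.abs(bounds_ap - k.ap_position))) for k in kinks]
    )

    if len(flips) == 0:
        warnings.warn("no asymmetry flips present; colocalization undefined")
        return math.inf, 1.0

    def mean_dist(kb: np.ndarray) -> float:
        return float(np.mean(np.min(np.abs(kb[:, None] - flips[None, :]), axis=1)))

    observed = mean_dist(kink_bounds)

    rng = np.random.default_rng(seed)
    null_kb = rng.integers(0, n_boundaries, size=(n_perm, len(kinks)))
    null_d = np.min(
        np.abs(null_kb[:, :, None] - flips[None, None, :]), axis=2
    ).mean(axis=1)
    p = (1 + int(np.sum(null_d <= observed))) / (n_perm + 1)
    return observed, float(p)


def kinks_to_frame(records: list[KinkRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ap_position_um": [r.ap_position for r in records],
            "interior_angle_deg": [r.interior_angle for r in records],
            "plane": [r.plane for r in records],
        }
    )
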