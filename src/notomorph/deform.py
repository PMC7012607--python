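"""Per-centrum notochord deformation and vertebral symmetry indices.

During spine formation, vertebral bone grows concentrically around the
notochord and indents it dorsally and ventrally under each centrum.  A
healthy notochord, pressurised by its vacuolated cells, is compressed
symmetrically; loss of vacuole integrity lets bone indent one side more
deeply than the other.  This module quantifies that with the circle-fit
deformation index: a circle is fitted by least squares to the dorsal and to
the ventral contour of the notochord under each centrum, and the index

    D = -min(r_d, r_v) / max(r_d, r_v)

compares the two fitted radii.  D = -1 means symmetric compression
(equal radii); D -> 0 as one side flattens (its radius -> infinity).  The
signed asymmetry

    A = (r_v - r_d) / (r_v + r_d)

is positive when the dorsal indentation is tighter and negative when the
ventral one is; flips in the sign of A along the axis mark places where
the asymmetry changes orientation.  The same computation applied to the
outer dorsal/ventral contours of a centrum's bone outline gives the
vertebral symmetry index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import CentrumSpec
from .grids import LabelVolume

__all__ = [
    "SagittalProfile",
    "CentrumDeformation",
    "fit_circle",
    "deformation_index",
    "vertebral_symmetry_index",
    "canal_diameter",
    "profile_from_mask",
]

#: fitted radii larger than this multiple of the notochord radius are
#: treated as a flat (uncompressed) side and reported as +inf
FLAT_RADIUS_FACTOR = 10.0


@dataclass
class SagittalProfile:
    """Dorsal and ventral notochord (or centrum bone) contours in the
    sagittal plane, with the AP spans of the centra overlying them.

    ``dorsal`` and ``ventral`` are (N, 2) arrays of (ap, dv) points in µm,
    AP-sorted; ``midline_dv`` is the DV level of the notochord axis.
    """

    dorsal: np.ndarray
    ventral: np.ndarray
    centra: list[CentrumSpec] = field(default_factory=list)
    midline_dv: float = 0.0

    def __post_init__(self) -> None:
        self.dorsal = np.asarray(self.dorsal, dtype=float)
        self.ventral = np.asarray(self.ventral, dtype=float)
        for name, arr in (("dorsal", self.dorsal), ("ventral", self.ventral)):
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name} contour must be an (N, 2) array of (ap, dv)")
            if arr.shape[0] >= 2 and np.any(np.diff(arr[:, 0]) < 0):
                raise ValueError(f"{name} contour must be AP-sorted")

    def radius_estimate(self) -> float:
        """Half the median dorsal-ventral gap, a robust estimate of the
        uncompressed notochord radius."""
        ap = self.dorsal[:, 0]
        ventral_dv = np.interp(ap, self.ventral[:, 0], self.ventral[:, 1])
        gap = self.dorsal[:, 1] - ventral_dv
        return float(np.median(gap) / 2.0)


@dataclass
class CentrumDeformation:
    """Fitted radii and derived indices for one centrum.

    ``deformation_index`` is in [-1, 0] (-1 symmetric, 0 one side flat);
    ``signed_asymmetry`` is in [-1, 1], antisymmetric under swapping the
    dorsal and ventral sides.
    """

    centrum_index: int
    r_dorsal: float
    r_ventral: float
    deformation_index: float
    signed_asymmetry: float
    rms_dorsal: float = 0.0
    rms_ventral: float = 0.0
    ap_start: float = math.nan
    ap_end: float = math.nan


def fit_circle(points) -> tuple[np.ndarray, float, float]:
    """Algebraic (Kåsa) least-squares circle fit to 2D points.

    Solves the linear system ``2 x a + 2 y b + c = x² + y²`` for the
    center (a, b) and ``r = sqrt(c + a² + b²)``.  Exact on noiseless
    circular data.

    Parameters
    ----------
    points : (N, 2) array_like
        At least 3 points.

    Returns
    -------
    center : ndarray (2,)
        Fitted center; NaN when the points are collinear.
    radius : float
        Fitted radius; ``math.inf`` when the points are collinear within
        tolerance (a flat contour), in which case no exception is raised.
    rms_residual : float
        Root-mean-square of the radial residuals (point-to-line residuals
        in the collinear case).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array")
    if pts.shape[0] < 3:
        raise ValueError("circle fit needs at least 3 points")

    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    scale = max(svals[0], np.finfo(float).tiny)
    if svals[1] / scale < 1e-9:
        # collinear: flat-contour sentinel; residual is distance to the line
        return np.array([np.nan, np.nan]), math.inf, float(svals[1] / math.sqrt(len(pts)))

    a_mat = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    rhs = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0:
        return np.array([np.nan, np.nan]), math.inf, float("nan")
    radius = math.sqrt(r2)
    dists = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    rms = float(np.sqrt(np.mean((dists - radius) ** 2)))
    return np.array([cx, cy]), radius, rms


def indices_from_radii(r_dorsal: float, r_ventral: float) -> tuple[float, float]:
    """Deformation index D and signed asymmetry A from two fitted radii.

    D = -min(r)/max(r), 0 when either radius is infinite.  A is the limit
    of (r_v - r_d)/(r_v + r_d): 0 when both sides are flat, ±1 when exactly
    one is flat.
    """
    d_inf = math.isinf(r_dorsal)
    v_inf = math.isinf(r_ventral)
    if d_inf and v_inf:
        return 0.0, 0.0
    if d_inf:
        return 0.0, -1.0
    if v_inf:
        return 0.0, 1.0
    d = -min(r_dorsal, r_ventral) / max(r_dorsal, r_ventral)
    a = (r_ventral - r_dorsal) / (r_ventral + r_dorsal)
    return d, a


def _side_radius(
    points: np.ndarray,
    side: str,
    flat_threshold: float,
) -> tuple[float, float]:
    """Fit one side's contour window; return (radius, rms).

    The side is scored as an indentation only when the contour bows toward
    the midline: for the dorsal contour the fitted center must lie above
    the points (curve concave from above), for the ventral below.
    Otherwise the radius is the flat sentinel +inf.
    """
    center, radius, rms = fit_circle(points)
    if math.isinf(radius) or radius > flat_threshold:
        return math.inf, rms
    mean_dv = points[:, 1].mean()
    if side == "dorsal" and not center[1] > mean_dv:
        return math.inf, rms
    if side == "ventral" and not center[1] < mean_dv:
        return math.inf, rms
    return radius, rms


def deformation_index(
    profile: SagittalProfile,
    centrum_index: int,
    window_fraction: float = 0.6,
) -> CentrumDeformation:
    """Circle-fit notochord deformation index for one centrum.

    Circles are fitted separately to the dorsal and ventral contour points
    restricted to the central ``window_fraction`` of the centrum's AP span
    (excluding the flared ends near the prospective intervertebral discs),
    and combined into D and A as documented in the module docstring.

    Raises
    ------
    ValueError
        If either side has fewer than 3 contour samples in the window.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    try:
        centrum = profile.centra[centrum_index]
    except IndexError:
        raise IndexError(
            f"centrum_index {centrum_index} out of range "
            f"({len(profile.centra)} centra)"
        ) from None
    half = 0.5 * window_fraction * centrum.span
    lo, hi = centrum.center - half, centrum.center + half

    flat_threshold = FLAT_RADIUS_FACTOR * profile.radius_estimate()
    radii: dict[str, float] = {}
    rms: dict[str, float] = {}
    for side, contour in (("dorsal", profile.dorsal), ("ventral", profile.ventral)):
        sel = contour[(contour[:, 0] >= lo) & (contour[:, 0] <= hi)]
        if len(sel) < 3:
            raise ValueError(
                f"centrum {centrum_index}: only {len(sel)} {side} contour samples "
                f"in window [{lo:.1f}, {hi:.1f}] µm (need >= 3)"
            )
        radii[side], rms[side] = _side_radius(sel, side, flat_threshold)

    d, a = indices_from_radii(radii["dorsal"], radii["ventral"])
    return CentrumDeformation(
        centrum_index=centrum_index,
        r_dorsal=radii["dorsal"],
        r_ventral=radii["ventral"],
        deformation_index=d,
        signed_asymmetry=a,
        rms_dorsal=rms["dorsal"],
        rms_ventral=rms["ventral"],
        ap_start=centrum.ap_start,
        ap_end=centrum.ap_end,
    )


def vertebral_symmetry_index(
    bone_profile: SagittalProfile,
    centrum_index: int,
    window_fraction: float = 0.6,
) -> CentrumDeformation:
    """Vertebral symmetry index: the circle-fit index applied to the outer
    dorsal/ventral contours of a centrum's bone outline.

    An hourglass centrum whose waist curves identically on both sides
    scores -1; a flat-sided (cylindrical) centrum scores 0.  The
    computation is identical to :func:`deformation_index`; only the input
    contours differ (bone outline instead of notochord boundary).
    """
    return deformation_index(bone_profile, centrum_index, window_fraction)


def canal_diameter(vertebra_mask: LabelVolume, centrum_index: int) -> float:
    """Equivalent-circle diameter (µm) of the vertebral canal at
    mid-centrum.

    The canal is the background component fully enclosed by bone in the
    cross-section at the AP midpoint of the selected vertebra; its
    diameter is ``2 * sqrt(area / pi)``.  ``centrum_index`` is the 0-based
    ordinal of the vertebra in AP order.

    Raises
    ------
    ValueError
        If the bone does not enclose any background in that cross-section.
    """
    ids = vertebra_mask.ids()
    if len(ids) == 0:
        raise ValueError("vertebra mask contains no labels")
    # order vertebrae by AP centroid
    ap_centroids = ndimage.center_of_mass(
        np.ones(vertebra_mask.shape), vertebra_mask.labels, ids
    )
    order = np.argsort([c[0] for c in ap_centroids], kind="stable")
    try:
        label = ids[order[centrum_index]]
    except IndexError:
        raise IndexError(
            f"centrum_index {centrum_index} out of range ({len(ids)} vertebrae)"
        ) from None

    mask = vertebra_mask.labels == label
    ap_occupied = np.flatnonzero(mask.any(axis=(1, 2)))
    mid = int(ap_occupied[len(ap_occupied) // 2])
    bone2d = mask[mid]
    enclosed = ndimage.binary_fill_holes(bone2d) & ~bone2d
    if not enclosed.any():
        raise ValueError(
            f"vertebra {label}: no enclosed canal in cross-section ap index {mid}"
        )
    # keep the largest enclosed component (the canal lumen)
    comp, n = ndimage.label(enclosed)
    areas = np.bincount(comp.ravel())[1:]
    canal_voxels = areas.max()
    _, s_dv, s_lr = vertebra_mask.spacing
    area_um2 = float(canal_voxels) * s_dv * s_lr
    return 2.0 * math.sqrt(area_um2 / math.pi)


def profile_from_mask(
    mask2d: np.ndarray,
    spacing: tuple[float, float],
    centra: list[CentrumSpec] | None = None,
) -> SagittalProfile:
    """Extract dorsal/ventral contours from a 2D sagittal mask.

    The mask is indexed (ap, dv).  For every AP column containing
    foreground, the dorsal contour point is half a pixel above the topmost
    foreground pixel and the ventral point half a pixel below the
    bottommost one (the sub-pixel position of the boundary of a binary
    mask), in physical µm.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if mask2d.ndim != 2:
        raise ValueError("mask2d must be 2D (ap, dv)")
    s_ap, s_dv = float(spacing[0]), float(spacing[1])
    cols = np.flatnonzero(mask2d.any(axis=1))
    if cols.size == 0:
        raise ValueError("mask is empty")
    dorsal = []
    ventral = []
    for i in cols:
        dv_idx = np.flatnonzero(mask2d[i])
        ap = i * s_ap
        dorsal.append((ap, (dv_idx[-1] + 0.5) * s_dv))
        ventral.append((ap, (dv_idx[0] - 0.5) * s_dv))
    dorsal = np.asarray(dorsal)
    ventral = np.asarray(ventral)
    midline = float(np.median((dorsal[:, 1] + ventral[:, 1]) / 2.0))
    return SagittalProfile(
        dorsal=dorsal, ventral=ventral, centra=list(centra or []), midline_dv=midline
    )
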