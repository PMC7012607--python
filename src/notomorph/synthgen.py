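"""Ground-truthed synthetic notochord volumes and sagittal spine profiles.

The generator emulates the imaging data the morphometric pipeline is built
for, with known ground truth so every downstream stage can be tested
without real acquisitions:

* a tubular notochord of large ovoid vacuolated cells packed in a
  staircase pattern (consecutive cells alternate dorsal/ventral offsets
  and interdigitate), with either a stereotyped sinusoidal AP volume
  pattern (wild-type-like) or the same volumes shuffled along the axis
  (mutant-like);
* vacuole fragmentation: a fraction of cells replaced by several disjoint
  fragments whose summed volume is a fixed retention fraction of the
  parent volume;
* one nucleus per cell, either an oblate disc pressed against the outer
  cell boundary (high internal pressure) or a sphere at the cell centroid
  (collapsed pressure);
* a membrane channel bright on cell boundaries and a nucleus channel,
  both passed through a simple imaging model (Gaussian blur + additive
  Gaussian noise);
* 2D sagittal profiles of the notochord indented by hourglass centra with
  independently controllable dorsal/ventral arc radii, and spine
  centerlines with injected kinks of known angle and position.

All randomness derives from ``config.seed``; identical config and seed
give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import KinkSpec, SynthConfig
from .deform import SagittalProfile
from .grids import LabelVolume, VoxelGrid3D

__all__ = [
    "PackingError",
    "SyntheticNotochord",
    "build_notochord_volume",
    "build_spine_profile",
    "inject_axis_kinks",
]

# geometry constants of the staircase packing (fractions of the tube radius)
_DV_OFFSET_FRAC = 0.45   # dorsal/ventral offset of alternating cells
_RADIAL_AXIS_FRAC = 0.52  # radial semi-axes of each ovoid cell
_OVERSIZE = 1.05  # rasterization oversize factor; cells are trimmed back
#                   to their exact target voxel count afterwards
_MEMBRANE_INTENSITY = 200.0
_CYTOPLASM_INTENSITY = 10.0
_NUCLEUS_INTENSITY = 200.0
#: fraction of a centrum's AP span covered by the indentation arc
ARC_FRACTION = 0.7


class PackingError(ValueError):
    """Requested cells cannot be packed into the tube at the requested
    volumes; raised explicitly rather than silently truncating."""


@dataclass
class SyntheticNotochord:
    """Output bundle of :func:`build_notochord_volume`.

    ``notochord_mask`` is the full tube interior (the reference for
    radial nuclear positions); ``cell_labels`` are the individual
    vacuolated cells inside it.
    """

    membrane: VoxelGrid3D
    nucleus: VoxelGrid3D
    cell_labels: LabelVolume
    nucleus_labels: LabelVolume
    notochord_mask: LabelVolume
    truth: pd.DataFrame

    def __iter__(self):
        yield from (
            self.membrane,
            self.nucleus,
            self.cell_labels,
            self.nucleus_labels,
            self.truth,
        )


def _cell_layout(config: SynthConfig, rng: np.random.Generator):
    """Seed centers, target volumes and semi-axes for the staircase packing.

    Returns (centers (n,3) µm, target volumes, pattern values, a, b) where
    a is the AP semi-axis per cell and b the common radial semi-axis.
    """
    n = config.n_cells
    length = config.notochord_length
    radius = config.notochord_radius
    pitch = length / n
    b = _RADIAL_AXIS_FRAC * radius

    ap_nominal = (np.arange(n) + 0.5) * pitch
    pattern = np.array([config.volume_profile.pattern(ap) for ap in ap_nominal])
    if config.volume_profile.mode == "randomized":
        volumes = rng.permutation(pattern)
    else:
        volumes = pattern.copy()

    a = 3.0 * volumes / (4.0 * math.pi * b * b)
    if np.any(a >= pitch):
        worst = int(np.argmax(a))
        raise PackingError(
            f"cell {worst} needs AP semi-axis {a[worst]:.1f} µm >= cell pitch "
            f"{pitch:.1f} µm; reduce volumes or n_cells"
        )

    dv_off = np.where(np.arange(n) % 2 == 0, 1.0, -1.0) * _DV_OFFSET_FRAC * radius
    # small jitter keeps the lattice from being perfectly regular without
    # letting neighbouring ovoids collide
    ap = ap_nominal + rng.normal(0.0, 0.02 * pitch, n)
    dv = dv_off + rng.normal(0.0, 0.01 * radius, n)
    lr = rng.normal(0.0, 0.02 * radius, n)
    if n >= 2:
        # the first and last cell are inset so that (even oversized during
        # rasterization) they end exactly at the tube ends: the occupied AP
        # extent then equals the configured notochord length
        ap[0] = _OVERSIZE * a[0]
        ap[-1] = length - _OVERSIZE * a[-1]
    # radial fit check: every ovoid must stay inside the tube
    radial = np.hypot(dv, lr)
    if np.any(radial + b > radius):
        worst = int(np.argmax(radial + b))
        raise PackingError(
            f"cell {worst} extends to radius {(radial + b)[worst]:.1f} µm "
            f"outside the tube (radius {radius:.1f} µm)"
        )
    centers = np.column_stack([ap, dv, lr])
    return centers, volumes, pattern, a, b


def _make_grid(config: SynthConfig):
    s_ap, s_dv, s_lr = config.imaging.spacing
    margin = 4.0
    n_ap = int(round(config.notochord_length / s_ap)) + 1
    half = config.notochord_radius + margin
    n_dv = 2 * int(round(half / s_dv)) + 1
    n_lr = 2 * int(round(half / s_lr)) + 1
    shape = (n_ap, n_dv, n_lr)
    axis_dv = (n_dv // 2) * s_dv
    axis_lr = (n_lr // 2) * s_lr
    return shape, axis_dv, axis_lr


def _rasterize_cells(config, centers, a, b, shape, axis_dv, axis_lr):
    """Paint ovoid cells into a label volume.

    Each cell is painted as a slightly oversized ellipsoid (factor
    ``_OVERSIZE`` on both semi-axes); overlaps are resolved by nearest
    seed in the per-cell normalized ellipsoid metric, restricted to the
    tube interior.  Each cell is then trimmed back to exactly its target
    voxel count (dropping the outermost voxels first), so realized
    volumes track the generating pattern to within one voxel.
    """
    s_ap, s_dv, s_lr = config.imaging.spacing
    vox_vol = s_ap * s_dv * s_lr
    labels = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf, dtype=np.float64)

    dv_coords = np.arange(shape[1]) * s_dv - axis_dv
    lr_coords = np.arange(shape[2]) * s_lr - axis_lr
    radius2 = config.notochord_radius ** 2

    for i in range(len(centers)):
        cap, cdv, clr = centers[i]
        ai, bi = _OVERSIZE * a[i], _OVERSIZE * b
        lo_ap = max(0, int(math.floor((cap - ai) / s_ap)))
        hi_ap = min(shape[0], int(math.ceil((cap + ai) / s_ap)) + 1)
        lo_dv = max(0, int(math.floor((cdv + axis_dv - bi) / s_dv)))
        hi_dv = min(shape[1], int(math.ceil((cdv + axis_dv + bi) / s_dv)) + 1)
        lo_lr = max(0, int(math.floor((clr + axis_lr - bi) / s_lr)))
        hi_lr = min(shape[2], int(math.ceil((clr + axis_lr + bi) / s_lr)) + 1)

        ap_c = np.arange(lo_ap, hi_ap) * s_ap - cap
        dv_c = dv_coords[lo_dv:hi_dv] - cdv
        lr_c = lr_coords[lo_lr:hi_lr] - clr
        nd = (
            (ap_c[:, None, None] / ai) ** 2
            + (dv_c[None, :, None] / bi) ** 2
            + (lr_c[None, None, :] / bi) ** 2
        )
        tube = (
            dv_coords[lo_dv:hi_dv, None] ** 2 + lr_coords[None, lo_lr:hi_lr] ** 2
        ) <= radius2
        box = (slice(lo_ap, hi_ap), slice(lo_dv, hi_dv), slice(lo_lr, hi_lr))
        claim = (nd <= 1.0) & tube[None, :, :] & (nd < best[box])
        labels[box][claim] = i + 1
        best[box][claim] = nd[claim]

    # trim each cell to its exact target voxel count, outermost first
    volumes = 4.0 / 3.0 * math.pi * a * b * b
    for i in range(len(centers)):
        target_n = int(round(volumes[i] / vox_vol))
        vox = np.argwhere(labels == i + 1)
        if len(vox) > target_n:
            nd_vals = best[tuple(vox.T)]
            order = np.argsort(nd_vals, kind="stable")
            drop = vox[order[target_n:]]
            labels[tuple(drop.T)] = 0
    return labels


def _fragment_cells(config, labels, rng):
    """Replace a seeded subset of cells by Voronoi fragments shrunk to the
    configured volume retention.  Returns (labels, parent_of) where
    parent_of maps each final label to its parent cell label."""
    frag = config.fragmentation
    n = config.n_cells
    parent_of = {lab: lab for lab in range(1, n + 1)}
    n_frag_cells = int(round(frag.fraction_of_cells * n))
    if n_frag_cells == 0:
        return labels, parent_of

    spacing = np.asarray(config.imaging.spacing)
    frag_parents = np.sort(rng.choice(np.arange(1, n + 1), size=n_frag_cells, replace=False))
    next_label = n + 1
    k = frag.fragments_per_cell
    for parent in frag_parents:
        vox = np.argwhere(labels == parent)
        if len(vox) < k:
            raise PackingError(
                f"cell {parent} has only {len(vox)} voxels, cannot split into {k}"
            )
        seed_idx = rng.choice(len(vox), size=k, replace=False)
        seeds = vox[seed_idx] * spacing
        phys = vox * spacing
        # nearest fragment seed in physical distance
        d2 = ((phys[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)
        labels[tuple(vox.T)] = 0
        del parent_of[parent]
        for f in range(k):
            members = np.flatnonzero(assign == f)
            keep_n = int(round(frag.volume_retention * len(members)))
            if keep_n >= 1:
                order = np.argsort(d2[members, f], kind="stable")
                kept = vox[members[order[:keep_n]]]
                labels[tuple(kept.T)] = next_label
                parent_of[next_label] = int(parent)
            next_label += 1
    return labels, parent_of


def _place_nuclei(config, centers, b, shape, axis_dv, axis_lr, labels):
    """One nucleus per parent cell, per the configured nuclear mode."""
    s_ap, s_dv, s_lr = config.imaging.spacing
    spacing = (s_ap, s_dv, s_lr)
    nuc_labels = np.zeros(shape, dtype=np.int32)
    mode = config.nuclei.mode
    vol = config.nuclei.volume

    if mode == "central_sphere":
        r = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)
        semi = {"r": r}
    else:  # peripheral_disc: oblate spheroid, short:long = 1:4
        c_long = (3.0 * vol / math.pi) ** (1.0 / 3.0)
        semi = {"long": c_long, "short": c_long / 4.0}

    for i, (cap, cdv, clr) in enumerate(centers):
        if mode == "central_sphere":
            center = np.array([cap, cdv, clr])
            _paint_ellipsoid(
                nuc_labels, i + 1, center, semi["r"], semi["r"], None, spacing,
                axis_dv, axis_lr,
            )
        else:
            radial = math.hypot(cdv, clr)
            if radial < 1e-9:
                u = np.array([0.0, 1.0, 0.0])
            else:
                u = np.array([0.0, cdv / radial, clr / radial])
            offset = b - semi["short"] - 0.5
            center = np.array([cap, cdv, clr]) + offset * u
            _paint_ellipsoid(
                nuc_labels, i + 1, center, semi["long"], semi["short"], u, spacing,
                axis_dv, axis_lr,
            )
    return nuc_labels


def _paint_ellipsoid(out, label, center, r_long, r_short, axis_u, spacing,
                     axis_dv, axis_lr):
    """Paint a sphere (axis_u None) or an oblate spheroid with its short
    axis along axis_u into ``out``."""
    s_ap, s_dv, s_lr = spacing
    cap, cdv, clr = center
    rmax = r_long
    lo_ap = max(0, int(math.floor((cap - rmax) / s_ap)))
    hi_ap = min(out.shape[0], int(math.ceil((cap + rmax) / s_ap)) + 1)
    lo_dv = max(0, int(math.floor((cdv + axis_dv - rmax) / s_dv)))
    hi_dv = min(out.shape[1], int(math.ceil((cdv + axis_dv + rmax) / s_dv)) + 1)
    lo_lr = max(0, int(math.floor((clr + axis_lr - rmax) / s_lr)))
    hi_lr = min(out.shape[2], int(math.ceil((clr + axis_lr + rmax) / s_lr)) + 1)

    ap_c = np.arange(lo_ap, hi_ap) * s_ap - cap
    dv_c = np.arange(lo_dv, hi_dv) * s_dv - axis_dv - cdv
    lr_c = np.arange(lo_lr, hi_lr) * s_lr - axis_lr - clr
    x = np.stack(
        np.meshgrid(ap_c, dv_c, lr_c, indexing="ij"), axis=-1
    )
    if axis_u is None:
        nd = (x ** 2).sum(axis=-1) / (r_long ** 2)
    else:
        t = x @ axis_u
        perp2 = (x ** 2).sum(axis=-1) - t ** 2
        nd = (t / r_short) ** 2 + perp2 / (r_long ** 2)
    box = (slice(lo_ap, hi_ap), slice(lo_dv, hi_dv), slice(lo_lr, hi_lr))
    region = out[box]
    region[(nd <= 1.0) & (region == 0)] = label


def _boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Voxels of a labelled instance that face a different label or the
    background (6-connectivity)."""
    fg = labels > 0
    bnd = np.zeros(labels.shape, dtype=bool)
    for ax in range(3):
        for shift in (1, -1):
            rolled = np.roll(labels, shift, axis=ax)
            diff = labels != rolled
            # roll wraps around; edge voxels of the volume count as boundary
            edge = [slice(None)] * 3
            edge[ax] = slice(0, 1) if shift == 1 else slice(-1, None)
            diff[tuple(edge)] = True
            bnd |= diff & fg
    return bnd


def _truth_table(config, labels, parent_of, volumes, pattern, parent_counts):
    """One row per final label.

    ``target_volume_um3`` is the volume assigned to the parent cell by the
    volume profile (shuffled values in randomized mode);
    ``pattern_volume_um3`` is the generating AP pattern evaluated at the
    parent's lattice slot; ``parent_volume_um3`` is the parent's realized
    volume before fragmentation.
    """
    vox_vol = float(np.prod(config.imaging.spacing))
    spacing = np.asarray(config.imaging.spacing)
    rows = []
    ids = np.unique(labels)
    ids = ids[ids != 0]
    objects = ndimage.find_objects(labels)
    counts = np.bincount(labels.ravel(), minlength=labels.max() + 1)
    for lab in ids:
        sl = objects[lab - 1]
        sub = labels[sl] == lab
        idx = np.argwhere(sub) + [s.start for s in sl]
        centroid = idx.mean(axis=0) * spacing
        parent = parent_of[int(lab)]
        rows.append(
            {
                "label": int(lab),
                "parent_label": int(parent),
                "is_fragment": int(lab) != int(parent),
                "ap_nominal_um": (parent - 0.5)
                * config.notochord_length
                / config.n_cells,
                "target_volume_um3": float(volumes[parent - 1]),
                "pattern_volume_um3": float(pattern[parent - 1]),
                "parent_volume_um3": float(parent_counts[parent] * vox_vol),
                "volume_um3": float(counts[lab] * vox_vol),
                "centroid_ap_um": float(centroid[0]),
                "centroid_dv_um": float(centroid[1]),
                "centroid_lr_um": float(centroid[2]),
                "n_voxels": int(counts[lab]),
            }
        )
    return pd.DataFrame(rows)


def build_notochord_volume(config: SynthConfig) -> SyntheticNotochord:
    """Generate a synthetic notochord acquisition with ground truth.

    Returns a :class:`SyntheticNotochord` with the membrane and nucleus
    intensity channels (blurred/noisy per ``config.imaging``), the
    ground-truth cell and nucleus label volumes, and a truth table with
    one row per final label (intact cell or fragment) recording parentage,
    realized volume and centroid.

    Raises
    ------
    PackingError
        If the requested cells cannot be packed into the tube.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape, axis_dv, axis_lr = _make_grid(config)

    centers, volumes, pattern, a, b = _cell_layout(config, rng)
    # centers are relative to the tube axis in dv/lr; shift handled in raster
    labels = _rasterize_cells(config, centers, a, b, shape, axis_dv, axis_lr)
    parent_counts = np.bincount(labels.ravel(), minlength=config.n_cells + 1)
    labels, parent_of = _fragment_cells(config, labels, rng)
    nuc_labels = _place_nuclei(config, centers, b, shape, axis_dv, axis_lr, labels)

    truth = _truth_table(config, labels, parent_of, volumes, pattern, parent_counts)

    membrane = np.zeros(shape, dtype=np.float32)
    membrane[labels > 0] = _CYTOPLASM_INTENSITY
    membrane[_boundary_mask(labels)] = _MEMBRANE_INTENSITY
    nucleus = np.zeros(shape, dtype=np.float32)
    nucleus[nuc_labels > 0] = _NUCLEUS_INTENSITY

    s = np.asarray(config.imaging.spacing)
    if config.imaging.blur_sigma > 0:
        sig = config.imaging.blur_sigma / s
        membrane = ndimage.gaussian_filter(membrane, sig)
        nucleus = ndimage.gaussian_filter(nucleus, sig)
    if config.imaging.noise_sigma > 0:
        membrane = membrane + rng.normal(0, config.imaging.noise_sigma, shape).astype(
            np.float32
        )
        nucleus = nucleus + rng.normal(0, config.imaging.noise_sigma, shape).astype(
            np.float32
        )

    # full tube interior, the reference geometry for radial positions
    dv_coords = np.arange(shape[1]) * s[1] - axis_dv
    lr_coords = np.arange(shape[2]) * s[2] - axis_lr
    tube2d = (
        dv_coords[:, None] ** 2 + lr_coords[None, :] ** 2
    ) <= config.notochord_radius ** 2
    tube = np.broadcast_to(tube2d, shape).astype(np.int32)

    spacing = tuple(config.imaging.spacing)
    return SyntheticNotochord(
        membrane=VoxelGrid3D(membrane, spacing),
        nucleus=VoxelGrid3D(nucleus, spacing),
        cell_labels=LabelVolume(labels, spacing),
        nucleus_labels=LabelVolume(nuc_labels, spacing),
        notochord_mask=LabelVolume(np.ascontiguousarray(tube), spacing),
        truth=truth,
    )


def build_spine_profile(config: SynthConfig, ap_step: float = 1.0) -> SagittalProfile:
    """Sagittal dorsal/ventral notochord contours indented by the
    configured centra.

    Between centra the contours sit at ±notochord_radius around the
    midline; under each centrum the contour follows an arc of exactly the
    specified circle radius over the central ``ARC_FRACTION`` of the span,
    bowing toward the midline.

    Raises
    ------
    ValueError
        If an indentation would be deeper than the notochord radius, or an
        arc radius is too small to span the required chord.
    """
    config.validate()
    radius = config.notochord_radius
    ap = np.arange(0.0, config.notochord_length + ap_step / 2, ap_step)
    dorsal = np.full_like(ap, radius)
    ventral = np.full_like(ap, -radius)

    for ci, centrum in enumerate(config.centra):
        half = 0.5 * ARC_FRACTION * centrum.span
        for side, r in (("dorsal", centrum.dorsal_radius),
                        ("ventral", centrum.ventral_radius)):
            if math.isinf(r):
                continue
            if r <= half:
                raise ValueError(
                    f"centrum {ci}: {side} radius {r} µm too small for the "
                    f"{2 * half:.1f} µm indentation arc chord"
                )
            sagitta = r - math.sqrt(r * r - half * half)
            if sagitta > radius:
                raise ValueError(
                    f"centrum {ci}: {side} indentation depth {sagitta:.1f} µm "
                    f"exceeds the notochord radius {radius} µm"
                )
            in_arc = np.abs(ap - centrum.center) <= half
            x = ap[in_arc] - centrum.center
            bulge = np.sqrt(r * r - x * x)
            if side == "dorsal":
                y0 = radius + math.sqrt(r * r - half * half)
                dorsal[in_arc] = y0 - bulge
            else:
                y0 = -radius - math.sqrt(r * r - half * half)
                ventral[in_arc] = y0 + bulge

    return SagittalProfile(
        dorsal=np.column_stack([ap, dorsal]),
        ventral=np.column_stack([ap, ventral]),
        centra=list(config.centra),
        midline_dv=0.0,
    )


def inject_axis_kinks(
    centerline: np.ndarray,
    kinks: list[KinkSpec],
    window: float = 150.0,
) -> np.ndarray:
    """Bend a straight(ish) centerline at the specified positions.

    At each kink position the polyline is bent by rotating everything
    posterior to it about the kink point, so the interior angle between
    the flanking directions equals the spec angle and arc length is
    preserved exactly.  A vertex is inserted at each kink position.

    Parameters
    ----------
    centerline : (N, 2) or (N, 3) array
        Ordered points (ap, dv[, lr]) in µm, strictly AP-monotone.
    kinks : list of KinkSpec
    window : float
        Minimum allowed separation between kinks (µm); the downstream
        angle measurement needs an unkinked window on each side.

    Raises
    ------
    ValueError
        If the input is not AP-monotone, two kinks are closer than
        ``window``, or a left-right kink is requested on a 2D centerline.
    """
    pts = np.asarray(centerline, dtype=float).copy()
    if pts.ndim != 2 or pts.shape[1] not in (2, 3):
        raise ValueError("centerline must be (N, 2) or (N, 3)")
    if np.any(np.diff(pts[:, 0]) <= 0):
        raise ValueError("centerline must be strictly AP-monotone before injection")
    if not kinks:
        return pts

    for k in kinks:
        k.validate()
    positions = [k.ap_position for k in kinks]
    order = np.argsort(positions, kind="stable")
    sorted_kinks = [kinks[i] for i in order]
    pos_sorted = [k.ap_position for k in sorted_kinks]
    if np.any(np.diff(pos_sorted) < window):
        raise ValueError(
            f"kinks closer than the {window} µm angle-measurement window"
        )

    # arc-length position of each kink on the original line equals its AP
    # position only for a straight axis; use arc length for generality
    def _cumlen(p):
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    cum0 = _cumlen(pts)
    ap0 = pts[:, 0]
    kink_arcs = np.interp(pos_sorted, ap0, cum0)

    for spec, s_kink in zip(sorted_kinks, kink_arcs):
        cum = _cumlen(pts)
        if s_kink <= cum[0] or s_kink >= cum[-1]:
            raise ValueError(
                f"kink position {spec.ap_position} µm outside the centerline"
            )
        # insert a vertex exactly at the kink arc position
        j = int(np.searchsorted(cum, s_kink))
        t = (s_kink - cum[j - 1]) / (cum[j] - cum[j - 1])
        vertex = pts[j - 1] + t * (pts[j] - pts[j - 1])
        head = pts[:j]
        tail = pts[j:]

        if spec.plane == "leftright" and pts.shape[1] == 2:
            raise ValueError("left-right kink needs a 3D centerline")
        deflection = math.radians(180.0 - spec.interior_angle)
        cos_d, sin_d = math.cos(deflection), math.sin(deflection)
        if pts.shape[1] == 2:
            rot = np.array([[cos_d, -sin_d], [sin_d, cos_d]])
        elif spec.plane == "dorsoventral":
            rot = np.array(
                [[cos_d, -sin_d, 0.0], [sin_d, cos_d, 0.0], [0.0, 0.0, 1.0]]
            )
        else:
            rot = np.array(
                [[cos_d, 0.0, -sin_d], [0.0, 1.0, 0.0], [sin_d, 0.0, cos_d]]
            )
        tail_rot = (tail - vertex) @ rot.T + vertex
        pts = np.vstack([head, vertex[None, :], tail_rot]) if not np.allclose(
            tail[0], vertex
        ) else np.vstack([head, vertex[None, :], tail_rot[1:]])

    return pts
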