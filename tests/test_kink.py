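"""Centerline extraction, kink angles/detection and the asymmetry-flip
colocalization test."""

import math
import warnings

import numpy as np
import pytest

from notomorph import kink, synthgen
from notomorph.config import KinkSpec
from notomorph.deform import CentrumDeformation


def straight_line(n=801):
    return np.column_stack([np.arange(float(n)), np.zeros(n)])


def bent_centerline(specs, n=1601):
    return kink.Centerline(
        points=synthgen.inject_axis_kinks(straight_line(n), specs)
    )


class TestExtractCenterline:
    def test_straight_tube(self):
        mask = np.zeros((120, 30, 30), dtype=bool)
        mask[:, 10:20, 12:18] = True
        cl = kink.extract_centerline(mask, (1.0, 1.0, 1.0))
        # collinear: residual of points from the straight chord < 1 voxel
        chord = cl.points[-1] - cl.points[0]
        chord = chord / np.linalg.norm(chord)
        rel = cl.points - cl.points[0]
        residual = np.linalg.norm(rel - np.outer(rel @ chord, chord), axis=1)
        assert residual.max() < 1.0
        assert cl.points[0, 0] <= 2.0
        assert cl.points[-1, 0] >= 117.0

    def test_bent_tube_passes_near_vertex(self):
        """An L-shaped tube's centerline passes within 2 voxels of the
        known bend vertex."""
        mask = np.zeros((100, 80), dtype=bool)
        for i in range(100):
            dv = 10 if i < 50 else 10 + (i - 50)  # 45° bend at ap = 50
            mask[i, dv - 4:dv + 5] = True
        cl = kink.extract_centerline(mask, (1.0, 1.0), smooth_window=3)
        vertex = np.array([50.0, 10.0])
        dists = np.linalg.norm(cl.points - vertex, axis=1)
        assert dists.min() < 2.0

    def test_disconnected_mask_counts_components(self):
        mask = np.zeros((60, 20), dtype=bool)
        mask[5:20, 5:15] = True
        mask[40:55, 5:15] = True
        with pytest.raises(ValueError, match="2"):
            kink.extract_centerline(mask, (1.0, 1.0))


class TestKinkAngle:
    def test_straight_is_180(self):
        cl = kink.Centerline(points=straight_line())
        assert kink.kink_angle(cl, 400.0, 150.0) == 180.0

    def test_right_angle_corner(self):
        pts = np.array([[0.0, 0.0], [200.0, 0.0], [200.0, 200.0]])
        cl = kink.Centerline(points=pts)
        assert kink.kink_angle(cl, 200.0, 100.0) == pytest.approx(90.0, abs=0.5)

    def test_generator_kink_and_rigid_invariance(self):
        cl = bent_centerline([KinkSpec(800.0, 150.0)])
        a0 = kink.kink_angle(cl, 800.0, 150.0)
        assert a0 == pytest.approx(150.0, abs=0.5)
        th = math.radians(37.0)
        rot = np.array(
            [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
        )
        cl_rot = kink.Centerline(points=cl.points @ rot.T + [31.0, -47.0])
        assert kink.kink_angle(cl_rot, 800.0, 150.0) == pytest.approx(a0, abs=1e-6)

    def test_reversal_invariance(self):
        cl = bent_centerline([KinkSpec(800.0, 140.0)])
        rev = kink.Centerline(points=cl.points[::-1])
        pos_rev = rev.arc_length - 800.0  # same physical point from the far end
        assert kink.kink_angle(rev, pos_rev, 150.0) == pytest.approx(
            kink.kink_angle(cl, 800.0, 150.0), abs=1e-6
        )

    def test_window_too_large_raises(self):
        cl = kink.Centerline(points=straight_line(100))
        with pytest.raises(ValueError, match="window"):
            kink.kink_angle(cl, 50.0, 60.0)


class TestDetectKinks:
    def test_straight_centerline_no_kinks(self):
        cl = kink.Centerline(points=straight_line(1001))
        assert kink.detect_kinks(cl, window=150.0, threshold_deg=160.0) == []

    def test_two_injected_kinks_recovered(self):
        """Two kinks separated by > 2 windows: both recovered at the
        injected positions ± window/2 with angles within 2°."""
        cl = bent_centerline([KinkSpec(500.0, 150.0), KinkSpec(1100.0, 120.0)])
        recs = kink.detect_kinks(cl, window=150.0, threshold_deg=170.0)
        assert len(recs) == 2
        assert recs[0].ap_position == pytest.approx(500.0, abs=75.0)
        assert recs[1].ap_position == pytest.approx(1100.0, abs=75.0)
        assert recs[0].interior_angle == pytest.approx(150.0, abs=2.0)
        assert recs[1].interior_angle == pytest.approx(120.0, abs=2.0)

    def test_sharpening_over_time_monotone(self):
        """A time series with monotonically decreasing injected angle
        reports monotonically decreasing measured angles."""
        measured = []
        for angle in (170.0, 160.0, 145.0, 125.0, 100.0):
            cl = bent_centerline([KinkSpec(800.0, angle)])
            recs = kink.detect_kinks(cl, window=150.0, threshold_deg=175.0)
            assert len(recs) == 1
            measured.append(recs[0].interior_angle)
        assert all(a > b for a, b in zip(measured, measured[1:]))

    def test_leftright_kink_plane_labelled(self):
        """A 3D centerline bent in the left-right plane is detected with
        the correct bending-plane label."""
        n = 1601
        line3 = np.column_stack(
            [np.arange(float(n)), np.zeros(n), np.zeros(n)]
        )
        bent = synthgen.inject_axis_kinks(
            line3, [KinkSpec(800.0, 140.0, plane="leftright")]
        )
        recs = kink.detect_kinks(
            kink.Centerline(points=bent), window=150.0, threshold_deg=170.0
        )
        assert len(recs) == 1
        assert recs[0].plane == "leftright"
        assert recs[0].interior_angle == pytest.approx(140.0, abs=2.0)

    def test_count_monotone_in_threshold(self):
        cl = bent_centerline([KinkSpec(500.0, 150.0), KinkSpec(1100.0, 165.0)])
        counts = [
            len(kink.detect_kinks(cl, window=150.0, threshold_deg=t))
            for t in (140.0, 160.0, 172.0)
        ]
        assert counts[0] <= counts[1] <= counts[2]


def make_deformations(signs, span=100.0):
    """AP-ordered deformations with given asymmetry signs; centrum i spans
    [i*span, (i+1)*span]."""
    return [
        CentrumDeformation(
            centrum_index=i,
            r_dorsal=50.0,
            r_ventral=60.0 if s > 0 else 40.0,
            deformation_index=-0.8,
            signed_asymmetry=0.1 * s,
            ap_start=i * span,
            ap_end=(i + 1) * span,
        )
        for i, s in enumerate(signs)
    ]


class TestFlipColocalization:
    def test_kinks_at_flips_score_zero_distance(self):
        """Flips after centra 5 and 12 with kinks at those boundaries:
        mean distance 0 and a small p-value."""
        signs = np.ones(30)
        signs[6:13] = -1  # flips at boundaries 5 and 12
        defs = make_deformations(signs)
        kinks = [
            kink.KinkRecord(ap_position=600.0, interior_angle=130.0,
                            plane="dorsoventral"),
            kink.KinkRecord(ap_position=1300.0, interior_angle=120.0,
                            plane="dorsoventral"),
        ]
        dist, p = kink.flip_colocalization(defs, kinks, n_perm=10_000, seed=0)
        assert dist == 0.0
        assert p < 0.05

    def test_no_flips_defined_result(self):
        defs = make_deformations(np.ones(10))
        kinks = [kink.KinkRecord(300.0, 120.0, "dorsoventral")]
        with pytest.warns(UserWarning):
            dist, p = kink.flip_colocalization(defs, kinks, n_perm=100, seed=0)
        assert math.isinf(dist)
        assert p == 1.0

    def test_null_calibration(self):
        """Uniformly re-placed kinks reject at the nominal 5% rate
        (± 0.02 over 1000 replicates).

        The axis needs enough centra for the distance-in-centrum-counts
        statistic to have fine support; with very short axes the discrete
        permutation p-value is visibly conservative."""
        signs = np.ones(60)
        signs[11:36] = -1  # flips at boundaries 10 and 35
        defs = make_deformations(signs)
        rng = np.random.default_rng(7)
        rejections = 0
        for i in range(1000):
            boundaries = rng.integers(0, 59, size=2)
            kinks = [
                kink.KinkRecord(
                    ap_position=(b + 1) * 100.0, interior_angle=130.0,
                    plane="dorsoventral",
                )
                for b in boundaries
            ]
            _, p = kink.flip_colocalization(defs, kinks, n_perm=199, seed=int(i))
            rejections += p <= 0.05
        assert rejections / 1000 == pytest.approx(0.05, abs=0.02)
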