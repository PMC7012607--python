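"""Circle fitting, deformation/symmetry indices and canal diameter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from notomorph import deform, synthgen
from notomorph.config import CentrumSpec, wildtype_config
from notomorph.grids import LabelVolume


def circumcircle(p1, p2, p3):
    """Closed-form circumscribed circle of three non-collinear points —
    the independent oracle for the least-squares fit on exact data."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = (
        (ax ** 2 + ay ** 2) * (by - cy)
        + (bx ** 2 + by ** 2) * (cy - ay)
        + (cx ** 2 + cy ** 2) * (ay - by)
    ) / d
    uy = (
        (ax ** 2 + ay ** 2) * (cx - bx)
        + (bx ** 2 + by ** 2) * (ax - cx)
        + (cx ** 2 + cy ** 2) * (bx - ax)
    ) / d
    r = math.hypot(ax - ux, ay - uy)
    return (ux, uy), r


class TestFitCircle:
    def test_circumscribed_triangle(self):
        center, radius, rms = deform.fit_circle([(0, 1), (1, 0), (0, -1)])
        assert center == pytest.approx((0.0, 0.0), abs=1e-12)
        assert radius == pytest.approx(1.0, abs=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_exact_recovery_on_noiseless_circle(self):
        theta = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        pts = np.column_stack([2 + 5 * np.cos(theta), 3 + 5 * np.sin(theta)])
        center, radius, rms = deform.fit_circle(pts)
        assert radius == pytest.approx(5.0, abs=1e-9)
        assert center == pytest.approx((2.0, 3.0), abs=1e-9)
        assert rms < 1e-9

    def test_noise_bias(self):
        """Radius bias < 1% of radius at noise σ = 1% of radius, averaged
        over 100 seeds."""
        theta = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        radii = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = np.column_stack(
                [2 + 5 * np.cos(theta), 3 + 5 * np.sin(theta)]
            ) + rng.normal(0, 0.05, (50, 2))
            _, r, _ = deform.fit_circle(pts)
            radii.append(r)
        assert np.mean(radii) == pytest.approx(5.0, abs=0.05)

    def test_collinear_returns_flat_sentinel(self):
        _, radius, _ = deform.fit_circle([(0, 0), (1, 1), (2, 2), (3, 3)])
        assert math.isinf(radius)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_three_point_circumcircle_equivalence(self, seed):
        """On exact 3-point data the least-squares fit equals the
        closed-form circumcircle."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-10, 10, (3, 2))
        (cx, cy), r = circumcircle(*pts)
        if r > 1e3:  # nearly collinear triples are the flat sentinel's job
            return
        center, radius, _ = deform.fit_circle(pts)
        assert radius == pytest.approx(r, rel=1e-6)
        assert center == pytest.approx((cx, cy), rel=1e-5, abs=1e-6)


def profile_with_radii(r_dorsal, r_ventral, span=120.0):
    cfg = wildtype_config()
    cfg.centra = [
        CentrumSpec(100.0, 100.0 + span, dorsal_radius=r_dorsal,
                    ventral_radius=r_ventral)
    ]
    return synthgen.build_spine_profile(cfg)


class TestDeformationIndex:
    def test_symmetric_compression_is_minus_one(self):
        d = deform.deformation_index(profile_with_radii(50.0, 50.0), 0)
        assert d.deformation_index == pytest.approx(-1.0, abs=1e-9)
        assert d.signed_asymmetry == pytest.approx(0.0, abs=1e-9)

    def test_two_to_one_radii(self):
        d = deform.deformation_index(profile_with_radii(50.0, 100.0), 0)
        assert d.deformation_index == pytest.approx(-0.5, abs=1e-6)
        assert d.signed_asymmetry == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_flat_ventral_sentinel(self):
        d = deform.deformation_index(profile_with_radii(50.0, math.inf), 0)
        assert d.deformation_index == 0.0
        assert abs(d.signed_asymmetry) == 1.0
        assert math.isinf(d.r_ventral)

    def test_swap_antisymmetry(self):
        """Swapping dorsal/ventral leaves D unchanged and negates A."""
        d1 = deform.deformation_index(profile_with_radii(50.0, 100.0), 0)
        d2 = deform.deformation_index(profile_with_radii(100.0, 50.0), 0)
        assert d1.deformation_index == pytest.approx(d2.deformation_index)
        assert d1.signed_asymmetry == pytest.approx(-d2.signed_asymmetry)

    def test_d_range_over_radius_grid(self):
        """Parameter recovery: fitted radii within 5% and D within 0.05 of
        the generator-implied value over a grid of radii."""
        for r_d in (30.0, 60.0, 90.0, 120.0):
            for r_v in (30.0, 60.0, 90.0, 120.0):
                prof = profile_with_radii(r_d, r_v, span=80.0)
                d = deform.deformation_index(prof, 0)
                assert d.r_dorsal == pytest.approx(r_d, rel=0.05)
                assert d.r_ventral == pytest.approx(r_v, rel=0.05)
                expected = -min(r_d, r_v) / max(r_d, r_v)
                assert d.deformation_index == pytest.approx(expected, abs=0.05)
                assert -1.0 <= d.deformation_index <= 0.0

    def test_too_few_samples_names_centrum(self):
        prof = profile_with_radii(50.0, 50.0)
        sparse = deform.SagittalProfile(
            dorsal=prof.dorsal[::400],
            ventral=prof.ventral[::400],
            centra=prof.centra,
        )
        with pytest.raises(ValueError, match="centrum 0"):
            deform.deformation_index(sparse, 0)

    def test_vertebral_symmetry_index_same_math(self):
        """The bone-outline symmetry index is the identical circle-fit
        computation: symmetric hourglass -> -1, 2:1 -> -0.5, flat -> 0."""
        assert deform.vertebral_symmetry_index(
            profile_with_radii(50.0, 50.0), 0
        ).deformation_index == pytest.approx(-1.0, abs=1e-9)
        assert deform.vertebral_symmetry_index(
            profile_with_radii(100.0, 50.0), 0
        ).deformation_index == pytest.approx(-0.5, abs=1e-6)
        assert deform.vertebral_symmetry_index(
            profile_with_radii(math.inf, math.inf), 0
        ).deformation_index == 0.0


class TestCanalDiameter:
    @staticmethod
    def annulus_volume(inner, outer, spacing):
        n = 2 * int(outer / spacing) + 7
        c = n // 2
        yy, xx = (np.indices((n, n)) - c) * spacing
        rr = np.hypot(yy, xx)
        ring = (rr >= inner) & (rr <= outer)
        vol = np.zeros((5, n, n), dtype=np.int32)
        vol[1:4] = ring
        return LabelVolume(vol, (spacing, spacing, spacing))

    def test_annulus_diameter(self):
        vol = self.annulus_volume(40.0, 55.0, 1.0)
        assert deform.canal_diameter(vol, 0) == pytest.approx(80.0, abs=2.0)

    def test_coarse_spacing_tolerance_scales(self):
        vol = self.annulus_volume(40.0, 55.0, 5.0)
        assert deform.canal_diameter(vol, 0) == pytest.approx(80.0, abs=10.0)

    def test_solid_cylinder_raises(self):
        vol = self.annulus_volume(0.0, 55.0, 1.0)
        with pytest.raises(ValueError, match="canal"):
            deform.canal_diameter(vol, 0)


class TestProfileFromMask:
    def test_straight_tube_contours(self):
        mask = np.zeros((50, 41), dtype=bool)
        mask[:, 8:33] = True  # dv indices 8..32
        prof = deform.profile_from_mask(mask, (2.0, 1.0))
        assert np.all(prof.dorsal[:, 1] == 32.5)
        assert np.all(prof.ventral[:, 1] == 7.5)
        assert np.all(prof.dorsal[:, 1] > prof.ventral[:, 1])
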