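"""Generator contracts: packing, fragmentation bookkeeping, determinism,
AP volume pattern fidelity, spine profiles and kink injection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from notomorph import deform, kink, synthgen
from notomorph.config import CentrumSpec, KinkSpec, wildtype_config

from conftest import small_config


class TestNotochordVolume:
    def test_wildtype_construction(self, wt_sample):
        """40 intact cells -> 40 disjoint labels and 40 nuclei, with
        background zero outside the tube."""
        labels = wt_sample.cell_labels
        assert len(labels.ids()) == 40
        assert len(wt_sample.nucleus_labels.ids()) == 40
        assert len(wt_sample.truth) == 40
        # everything labelled lies inside the tube mask
        outside = wt_sample.notochord_mask.labels == 0
        assert labels.labels[outside].max(initial=0) == 0
        assert wt_sample.nucleus_labels.labels[outside].max(initial=0) == 0

    def test_fragmentation_bookkeeping(self, mutant_sample):
        """Half the cells fragment into 4 pieces retaining 70% of the
        parent volume (within the 5% discretization allowance)."""
        t = mutant_sample.truth
        intact = t[~t.is_fragment]
        frags = t[t.is_fragment]
        assert len(intact) == 20
        assert len(frags) == 20 * 4
        per_parent = frags.groupby("parent_label").agg(
            total=("volume_um3", "sum"), parent=("parent_volume_um3", "first")
        )
        ratio = per_parent.total / per_parent.parent
        assert np.all(np.abs(ratio - 0.7) < 0.05 * 0.7)

    def test_fragments_disjoint_from_everything(self, mutant_sample):
        """Labels are unique instances: total labelled voxels equal the
        sum of per-label counts (no overlap is representable, but the
        truth table must agree with the volume)."""
        t = mutant_sample.truth
        voxels = (mutant_sample.cell_labels.labels > 0).sum()
        assert int(t.n_voxels.sum()) == int(voxels)

    def test_seed_determinism(self):
        a = synthgen.build_notochord_volume(small_config(seed=7))
        b = synthgen.build_notochord_volume(small_config(seed=7))
        assert np.array_equal(a.cell_labels.labels, b.cell_labels.labels)
        assert np.array_equal(a.membrane.data, b.membrane.data)
        assert np.array_equal(a.nucleus.data, b.nucleus.data)
        assert a.truth.equals(b.truth)

    def test_different_seed_differs(self):
        a = synthgen.build_notochord_volume(small_config(seed=1))
        b = synthgen.build_notochord_volume(small_config(seed=2))
        assert not np.array_equal(a.cell_labels.labels, b.cell_labels.labels)

    @pytest.mark.parametrize("seed", range(5))
    def test_stereotyped_pattern_rank_fidelity(self, seed):
        """Realized volumes ordered by AP centroid follow the generating
        pattern with Spearman correlation exactly 1."""
        s = synthgen.build_notochord_volume(small_config(seed=seed))
        t = s.truth.sort_values("centroid_ap_um")
        rho = spearmanr(t.volume_um3, t.pattern_volume_um3).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_randomized_pattern_decorrelated(self):
        """Randomized mode shuffles volumes along the axis: correlation
        with the pattern is near zero for at least 9/10 seeds."""
        hits = 0
        for seed in range(10):
            cfg = small_config(seed=seed)
            cfg.volume_profile.mode = "randomized"
            s = synthgen.build_notochord_volume(cfg)
            t = s.truth.sort_values("centroid_ap_um")
            rho = spearmanr(t.volume_um3, t.pattern_volume_um3).statistic
            hits += abs(rho) < 0.5
        assert hits >= 9

    def test_packing_failure_is_explicit(self):
        cfg = small_config()
        cfg.volume_profile.baseline = 80000.0  # cannot fit at this pitch
        with pytest.raises(synthgen.PackingError):
            synthgen.build_notochord_volume(cfg)


class TestSpineProfile:
    def test_arc_matches_requested_radius(self):
        """Contour points under a centrum lie on a circle of exactly the
        configured radius (checked with the circle-fit oracle)."""
        cfg = wildtype_config()
        cfg.centra = [CentrumSpec(100.0, 220.0, dorsal_radius=50.0,
                                  ventral_radius=50.0)]
        prof = synthgen.build_spine_profile(cfg)
        c = cfg.centra[0]
        half = 0.5 * synthgen.ARC_FRACTION * c.span
        sel = prof.dorsal[np.abs(prof.dorsal[:, 0] - c.center) <= half - 1]
        _, radius, rms = deform.fit_circle(sel)
        assert radius == pytest.approx(50.0, abs=1e-6)
        assert rms < 1e-6

    def test_zero_centra_straight(self):
        cfg = wildtype_config()
        prof = synthgen.build_spine_profile(cfg)
        assert np.all(prof.dorsal[:, 1] == cfg.notochord_radius)
        assert np.all(prof.ventral[:, 1] == -cfg.notochord_radius)

    def test_flat_side_stays_straight(self):
        cfg = wildtype_config()
        cfg.centra = [CentrumSpec(100.0, 220.0, dorsal_radius=50.0,
                                  ventral_radius=math.inf)]
        prof = synthgen.build_spine_profile(cfg)
        assert np.all(prof.ventral[:, 1] == -cfg.notochord_radius)
        assert prof.dorsal[:, 1].min() < cfg.notochord_radius

    def test_too_deep_indentation_errors(self):
        cfg = wildtype_config()
        # arc chord 105 µm, radius 53 µm -> sagitta ≈ 45.7 µm > tube radius
        cfg.centra = [CentrumSpec(100.0, 250.0, dorsal_radius=53.0)]
        with pytest.raises(ValueError):
            synthgen.build_spine_profile(cfg)


class TestKinkInjection:
    @staticmethod
    def straight(n=801):
        return np.column_stack([np.arange(float(n)), np.zeros(n)])

    def test_empty_kink_list_identity(self):
        line = self.straight()
        out = synthgen.inject_axis_kinks(line, [])
        assert np.array_equal(out, line)

    @pytest.mark.parametrize("angle", [150.0, 90.0])
    def test_injected_angle_measured_back(self, angle):
        bent = synthgen.inject_axis_kinks(
            self.straight(), [KinkSpec(ap_position=400.0, interior_angle=angle)]
        )
        cl = kink.Centerline(points=bent)
        assert kink.kink_angle(cl, 400.0, 150.0) == pytest.approx(angle, abs=0.5)

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(angle=st.floats(min_value=35.0, max_value=175.0))
    def test_angle_roundtrip_property(self, angle):
        """Any representable interior angle survives injection +
        measurement to within 0.5 degrees, and arc length is preserved."""
        line = self.straight()
        bent = synthgen.inject_axis_kinks(
            line, [KinkSpec(ap_position=400.0, interior_angle=angle)]
        )
        cl = kink.Centerline(points=bent)
        assert kink.kink_angle(cl, 400.0, 120.0) == pytest.approx(angle, abs=0.5)
        assert cl.arc_length == pytest.approx(800.0, rel=0.01)

    def test_kinks_too_close_error(self):
        with pytest.raises(ValueError, match="closer"):
            synthgen.inject_axis_kinks(
                self.straight(),
                [KinkSpec(300.0, 150.0), KinkSpec(380.0, 140.0)],
                window=150.0,
            )

    def test_non_monotone_input_rejected(self):
        line = self.straight(50)
        line[10, 0] = line[9, 0]
        with pytest.raises(ValueError, match="monotone"):
            synthgen.inject_axis_kinks(line, [KinkSpec(20.0, 150.0)])
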