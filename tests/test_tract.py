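"""Tract lesionometry: components, fractions, severity calls, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cstlesion import maps, phantom, tract


def _zmap(values, excluded=None):
    values = np.asarray(values, dtype=float)
    if excluded is None:
        excluded = ~np.isfinite(values)
    return maps.ZScoreMap(values=np.where(excluded, np.nan, values),
                          metric="MTR", excluded_mask=excluded)


class TestFunctionalSide:
    def test_right_upper_limb(self):
        sel = tract.map_functional_side("right upper")
        assert sel.brain_side == "left"
        assert sel.sc_side == "right"
        assert sel.sc_extent == "C1_C7"

    def test_left_lower_limb(self):
        sel = tract.map_functional_side("left lower")
        assert sel.brain_side == "right"
        assert sel.sc_side == "left"
        assert sel.sc_extent == "full"

    def test_global_analysis_pools_both_sides(self):
        sel = tract.map_functional_side("edss")
        assert sel.brain_side == "both" and sel.sc_side == "both"
        assert sel.sc_extent == "full"

    def test_malformed_limb_rejected(self):
        with pytest.raises(ValueError):
            tract.map_functional_side("middle limb")

    def test_upper_limb_roi_stops_at_c7(self, space):
        sel = tract.map_functional_side("left upper")
        roi = tract.functional_roi_mask(space, sel)
        thoracic = space.region_mask("thoracic_T1_T10")
        assert not np.any(roi & thoracic)


class TestComponents:
    def test_two_disjoint_blobs(self, space):
        mask = np.zeros(space.shape, bool)
        mask[5:8, 10:13, 20:23] = True
        mask[5:8, 10:13, 60:63] = True
        comps = tract.label_lesion_components(mask, space)
        assert len(comps) == 2

    def test_corner_touching_voxels_merge_under_26_connectivity(self, space):
        mask = np.zeros(space.shape, bool)
        mask[5, 10, 20] = True
        mask[6, 11, 21] = True  # touches only at a corner
        comps = tract.label_lesion_components(mask, space)
        assert len(comps) == 1

    def test_empty_mask(self, space):
        assert tract.label_lesion_components(np.zeros(space.shape, bool), space) == []

    def test_portion_majority_assignment(self, space):
        # lesion straddling the brainstem/cervical boundary, mostly cervical
        b0, b1 = space.portion_bounds["cervical_C1_C7"]
        mask = np.zeros(space.shape, bool)
        cx, cy = 6, 12  # inside the left tube
        mask[cx, cy, b0 - 1:b0 + 3] = True
        comps = tract.label_lesion_components(mask, space)
        assert comps[0].portion == "cervical_C1_C7"
        assert comps[0].side == "left"


class TestLesionVolumeFraction:
    def test_formula(self):
        lesion = np.zeros((10, 10, 1), bool)
        lesion[:1, :10] = True  # 10 voxels
        tract_mask = np.ones((10, 10, 1), bool)  # 100-voxel ROI
        lesion[1:, :] = False
        assert tract.lesion_volume_fraction(lesion, tract_mask) == pytest.approx(10.0)

    def test_disjoint_masks(self):
        lesion = np.zeros((4, 4, 4), bool)
        lesion[0, 0, 0] = True
        roi = np.zeros((4, 4, 4), bool)
        roi[3, 3, 3] = True
        assert tract.lesion_volume_fraction(lesion, roi) == 0.0

    def test_empty_tract_rejected(self):
        with pytest.raises(ValueError):
            tract.lesion_volume_fraction(np.ones((2, 2, 2), bool),
                                         np.zeros((2, 2, 2), bool))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_brute_force_oracle(self, seed):
        """Vectorized fraction equals an explicit voxel loop, exactly."""
        rng = np.random.default_rng(seed)
        lesion = rng.random((16, 16, 16)) < 0.2
        roi = rng.random((16, 16, 16)) < 0.4
        if not roi.any():
            roi[0, 0, 0] = True
        inside = 0
        total = 0
        for idx in np.ndindex(16, 16, 16):
            if roi[idx]:
                total += 1
                if lesion[idx]:
                    inside += 1
        assert tract.lesion_volume_fraction(lesion, roi) == inside / total * 100.0


class TestRoiMean:
    def test_constant_map(self):
        assert tract.roi_mean(np.full((3, 3, 3), 42.0),
                              np.ones((3, 3, 3), bool)) == 42.0

    def test_half_and_half(self):
        vals = np.full((2, 2, 2), 40.0)
        vals[1] = 44.0
        assert tract.roi_mean(vals, np.ones((2, 2, 2), bool)) == 42.0

    def test_poisoned_invalid_voxels_ignored(self):
        vals = np.full((3, 3, 3), 42.0)
        vals[0, 0, 0] = np.nan  # carries a sentinel; 999 would distort the mean
        q = maps.QuantMap(vals)
        q.values[~q.validity_mask] = np.nan
        assert tract.roi_mean(q, np.ones((3, 3, 3), bool)) == 42.0

    def test_all_invalid_rejected(self):
        with pytest.raises(ValueError):
            tract.roi_mean(np.full((2, 2, 2), np.nan), np.ones((2, 2, 2), bool))


class TestSeverity:
    def _one_component(self, space):
        mask = np.zeros(space.shape, bool)
        mask[5:8, 11:14, 60:64] = True  # inside the left tube
        return mask, tract.label_lesion_components(mask, space)

    @pytest.mark.parametrize(
        "z,direction,expected",
        [
            (-3.0, "low", True),
            (-1.0, "low", False),
            (-1.96, "low", False),  # strict inequality at the threshold
            (3.0, "high", True),
            (-3.0, "high", False),
        ],
    )
    def test_threshold_rule(self, space, z, direction, expected):
        mask, comps = self._one_component(space)
        zmap = _zmap(np.full(space.shape, z))
        calls = tract.classify_lesion_severity(
            comps, zmap, space.tract_mask("both"), direction=direction
        )
        assert calls[0].severe is expected
        assert calls[0].mean_z == pytest.approx(z)

    def test_fully_excluded_component_flagged(self, space):
        mask, comps = self._one_component(space)
        zmap = _zmap(np.full(space.shape, -3.0), excluded=np.ones(space.shape, bool))
        calls = tract.classify_lesion_severity(comps, zmap, space.tract_mask("both"))
        assert not calls[0].classifiable
        assert not calls[0].severe

    def test_deepening_never_unflags_severe(self, space, atlas):
        """Monotonicity: deeper planted severity keeps the severe call."""
        radii = (2.0, 2.0, 4.0)
        severe_flags = []
        for z in (-2.5, -3.0, -3.5, -4.0):
            spec = phantom.LesionSpec(centre=(6, 12, 60), radii=radii,
                                      severity_z=z, side="left")
            p = phantom.simulate_patient(space, [spec], seed=42)  # fixed noise
            zmap = maps.compute_zscore_map(maps.QuantMap(p.quant_maps["MTR"]), atlas)
            comps = tract.label_lesion_components(p.lesion_mask, space)
            calls = tract.classify_lesion_severity(comps, zmap,
                                                   space.tract_mask("both"))
            severe_flags.append(calls[0].severe)
        assert severe_flags == sorted(severe_flags)  # False never follows True


class TestAbnormalAreas:
    def test_in_lesion_attribution(self, space):
        z = np.zeros(space.shape)
        lesion = np.zeros(space.shape, bool)
        z[5:8, 11:14, 60:63] = -3.0
        lesion[5:8, 11:14, 60:63] = True
        areas, frac = tract.abnormal_zscore_areas(
            _zmap(z), space.tract_mask("both"), lesion
        )
        assert len(areas) == 1 and areas[0].in_lesion
        assert frac == 100.0

    def test_extra_lesional_area(self, space):
        z = np.zeros(space.shape)
        z[5:8, 11:14, 60:63] = -3.0
        areas, frac = tract.abnormal_zscore_areas(
            _zmap(z), space.tract_mask("both"), np.zeros(space.shape, bool)
        )
        assert len(areas) == 1 and not areas[0].in_lesion
        assert frac == 0.0

    def test_no_areas_gives_nan_fraction(self, space):
        areas, frac = tract.abnormal_zscore_areas(
            _zmap(np.zeros(space.shape)), space.tract_mask("both"),
            np.zeros(space.shape, bool)
        )
        assert areas == [] and np.isnan(frac)


class TestProfile:
    def test_half_slice_lesion(self, space):
        tract_mask = space.tract_mask("left")
        axis = space.axis_is
        z0 = 60
        sl = [slice(None)] * 3
        sl[axis] = z0
        plane = tract_mask[tuple(sl)]
        lesion = np.zeros(space.shape, bool)
        coords = np.argwhere(plane)
        half = coords[: len(coords) // 2]
        for c in half:
            idx = list(c)
            idx.insert(axis, z0)
            lesion[tuple(idx)] = True
        profile = tract.tract_profile(lesion, _zmap(np.zeros(space.shape)),
                                      tract_mask, space, side="left")
        rec = profile.records.set_index("slice")
        assert rec.loc[z0, "pct_damaged"] == pytest.approx(
            100.0 * len(half) / len(coords)
        )
        assert (rec.drop(index=z0)["pct_damaged"] == 0).all()

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_conservation_and_bounds(self, seed):
        """Per-slice lesion counts sum to the total; fractions in [0, 100]."""
        space = phantom.build_phantom_space(shape=(16, 16, 40))
        rng = np.random.default_rng(seed)
        lesion = rng.random(space.shape) < 0.1
        tract_mask = space.tract_mask("both")
        profile = tract.tract_profile(lesion, _zmap(np.zeros(space.shape)),
                                      tract_mask, space)
        assert profile.records["n_lesion"].sum() == (lesion & tract_mask).sum()
        assert profile.records["pct_damaged"].between(0, 100).all()

    def test_planted_lesions_cover_expected_slices(self, space, atlas):
        specs = [
            phantom.LesionSpec(centre=(6, 12, 30), radii=(2.0, 2.0, 3.0),
                               severity_z=-3.0, side="left"),
            phantom.LesionSpec(centre=(6, 12, 90), radii=(2.0, 2.0, 3.0),
                               severity_z=-1.0, side="left"),
        ]
        p = phantom.simulate_patient(space, specs, seed=9)
        zmap = maps.compute_zscore_map(maps.QuantMap(p.quant_maps["MTR"]), atlas)
        profile = tract.tract_profile(p.lesion_mask, zmap,
                                      space.tract_mask("left"), space, side="left")
        rec = profile.records.set_index("slice")
        damaged = set(rec.index[rec["pct_damaged"] > 0])
        expected = set(range(27, 34)) | set(range(87, 94))
        assert damaged <= expected
        assert {30, 90} <= damaged


class TestExtralesional:
    def test_no_lesion_equals_roi_mean(self, space):
        vals = np.full(space.shape, 40.0)
        roi = space.tract_mask("both")
        assert tract.extralesional_mean(vals, roi, np.zeros(space.shape, bool)) == \
            tract.roi_mean(vals, roi)

    def test_lesion_voxels_excluded(self, space):
        vals = np.full(space.shape, 40.0)
        lesion = np.zeros(space.shape, bool)
        lesion[5:8, 11:14, 60:64] = True
        vals[lesion] = 30.0
        assert tract.extralesional_mean(vals, space.tract_mask("both"), lesion) == 40.0

    def test_whole_tract_lesion_rejected(self, space):
        roi = space.tract_mask("both")
        with pytest.raises(ValueError):
            tract.extralesional_mean(np.ones(space.shape), roi, roi)


class TestSeveritySummary:
    def _call(self, severe, portion="cervical_C1_C7"):
        return tract.SeverityCall(0, -3.0 if severe else -1.0, severe, "low",
                                  1.96, portion=portion)

    def test_printed_count_bookkeeping(self):
        """84 severe of 325 lesions across 70 profiles -> 25.8% severe."""
        per_profile = []
        lesions = [self._call(True)] * 84 + [self._call(False)] * 241
        # distribute the 325 lesions over 61 lesioned + 9 empty profiles
        for i in range(61):
            per_profile.append(lesions[i::61])
        per_profile.extend([[]] * 9)
        s = tract.severity_summary(per_profile)
        assert s["n_lesions"] == 325 and s["n_severe"] == 84
        assert round(s["pct_severe"], 1) == 25.8
        assert round(s["pct_profiles_with_lesion"]) == 87

    def test_empty_cohort_flagged(self):
        s = tract.severity_summary([[], [], []])
        assert s["empty"] and s["pct_severe"] == 0.0

    def test_location_breakdown(self):
        calls = [
            [self._call(True, "brain"), self._call(True, "cervical_C1_C7"),
             self._call(True, "thoracic_T1_T10"), self._call(False, "brain")]
        ]
        s = tract.severity_summary(calls)
        loc = s["severe_location"]
        assert loc["pct_brain"] == pytest.approx(100 / 3)
        assert loc["pct_sc"] == pytest.approx(200 / 3)
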