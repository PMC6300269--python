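"""Densitometry, parenchymal masking, ROI geometry and vertical distances."""

import numpy as np
import pytest

from bronchmech.morphometry import (
    DEFAULT_CONSTANTS,
    DensitometryConstants,
    build_parenchyma_mask,
    delta_h,
    equivalent_diameter,
    expansion,
    expansion_bounds,
    gas_fraction,
    lung_expansion,
    peribronchial_roi,
    sphere_mask,
)


class TestGasFraction:
    @pytest.mark.parametrize("hu, expected", [(65.0, 0.0), (-1000.0, 1.0), (-467.5, 0.5)])
    def test_reference_values(self, hu, expected):
        assert gas_fraction(hu) == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing_in_hu(self):
        hu = np.linspace(-1000, 65, 200)
        f = gas_fraction(hu)
        assert np.all(np.diff(f) < 0)

    def test_out_of_range_policies(self):
        assert gas_fraction(200.0, out_of_range="clamp") == 0.0
        with pytest.raises(ValueError):
            gas_fraction(200.0, out_of_range="raise")

    def test_constants_validation(self):
        with pytest.raises(ValueError):
            DensitometryConstants(mask_lo=-300.0)


class TestExpansion:
    @pytest.mark.parametrize(
        "hu, expected",
        [(-467.5, 1.0), (-400.0, 0.775), (-950.0, 20.3)],
    )
    def test_uniform_roi_closed_form(self, hu, expected):
        vol = np.full((4, 4, 4), hu)
        mask = np.ones_like(vol, dtype=bool)
        assert expansion(vol, mask) == pytest.approx(expected, abs=1e-9)

    def test_bounds_of_parenchymal_window(self):
        lo, hi = expansion_bounds()
        assert lo == pytest.approx(0.775, abs=1e-9)
        assert hi == pytest.approx(20.3, abs=1e-9)
        hu = np.random.default_rng(0).uniform(-950, -400, size=1000)
        e = np.array([expansion(np.array([[[v]]]), np.ones((1, 1, 1), bool)) for v in hu[:50]])
        assert np.all((e >= lo - 1e-9) & (e <= hi + 1e-9))

    def test_empty_roi_and_pure_air_rejected(self):
        vol = np.full((2, 2, 2), -500.0)
        with pytest.raises(ValueError):
            expansion(vol, np.zeros_like(vol, bool))
        vol[0, 0, 0] = -1000.0
        with pytest.raises(ValueError):
            expansion(vol, np.ones_like(vol, bool))

    def test_lung_expansion_is_voxel_mean_of_two_segments(self):
        # halves at E = 1 and E = 3 -> whole-lung E = 2
        hu1 = 65.0 - 0.5 * 1065.0
        hu3 = 65.0 - 0.75 * 1065.0
        vol = np.concatenate([np.full((4, 4, 2), hu1), np.full((4, 4, 2), hu3)], axis=2)
        assert lung_expansion(vol, np.ones_like(vol, bool)) == pytest.approx(2.0, abs=1e-9)


class TestParenchymaMask:
    def test_window_inclusive_and_trees_removed(self):
        vol = np.full((3, 3, 3), -700.0)
        vol[0, 0, 0] = -399.0  # just above the window
        vol[0, 0, 1] = -400.0  # boundary, included
        vol[0, 0, 2] = -950.0  # boundary, included
        vol[1, 1, 1] = -951.0  # just below
        lung = np.ones_like(vol, bool)
        airway = np.zeros_like(lung)
        vessel = np.zeros_like(lung)
        airway[2, 2, 2] = True
        mask = build_parenchyma_mask(lung, airway, vessel, vol)
        assert not mask[0, 0, 0] and not mask[1, 1, 1]
        assert mask[0, 0, 1] and mask[0, 0, 2]
        assert not mask[2, 2, 2]

    def test_empty_mask_is_an_error(self):
        vol = np.full((2, 2, 2), -200.0)
        ones = np.ones_like(vol, bool)
        with pytest.raises(ValueError):
            build_parenchyma_mask(ones, ~ones, ~ones, vol)


class TestPeribronchialROI:
    def test_sphere_diameter_is_four_equivalent_diameters(self):
        assert 4 * equivalent_diameter(20.0) == pytest.approx(20.185, abs=1e-3)

    def test_membership_matches_brute_force_scan(self):
        shape, spacing = (20, 18, 16), (1.5, 1.5, 1.5)
        center, d = (14.0, 13.0, 11.0), 17.0
        fast = sphere_mask(shape, spacing, center, d)
        slow = np.zeros(shape, bool)
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    p = np.array([i, j, k]) * np.array(spacing)
                    slow[i, j, k] = np.sum((p - center) ** 2) <= (d / 2) ** 2
        assert np.array_equal(fast, slow)

    @pytest.fixture()
    def uniform_volume(self):
        vol = np.full((40, 40, 40), -467.5)
        return vol, np.ones_like(vol, dtype=bool), (1.5, 1.5, 1.5)

    def test_tissue_plus_gas_equals_geometric_volume(self, uniform_volume):
        vol, mask, sp = uniform_volume
        roi = peribronchial_roi(vol, mask, (30.0, 30.0, 30.0), 20.0, sp)
        vox_ml = np.prod(sp) / 1000.0
        assert roi.tissue_volume_ml + roi.gas_volume_ml == pytest.approx(
            roi.n_voxels * vox_ml, abs=1e-9
        )
        assert roi.e_pb == pytest.approx(1.0, abs=1e-12)

    def test_reference_equal_to_own_tissue_is_a_fixed_point(self, uniform_volume):
        vol, mask, sp = uniform_volume
        base = peribronchial_roi(vol, mask, (30.0, 30.0, 30.0), 20.0, sp)
        again = peribronchial_roi(
            vol, mask, (30.0, 30.0, 30.0), 20.0, sp,
            reference_tissue_ml=base.tissue_volume_ml,
        )
        assert abs(again.tissue_volume_ml / base.tissue_volume_ml - 1) <= 0.05

    def test_matched_diameter_scales_with_expansion_change(self, uniform_volume):
        """Uniform tissue fraction: matching tissue across an expansion change
        grows the diameter by the cube root of the tissue-fraction ratio."""
        vol_b, mask, sp = uniform_volume
        base = peribronchial_roi(vol_b, mask, (30.0, 30.0, 30.0), 20.0, sp)
        # more expanded state: E = 3 -> tissue fraction 0.25 vs 0.5
        vol_t = np.full_like(vol_b, 65.0 - 0.75 * 1065.0)
        matched = peribronchial_roi(
            vol_t, mask, (30.0, 30.0, 30.0), 20.0, sp,
            reference_tissue_ml=base.tissue_volume_ml,
        )
        assert matched.diameter_mm / base.diameter_mm == pytest.approx(
            2.0 ** (1 / 3), rel=0.06
        )

    def test_unreachable_reference_reports_mismatch(self, uniform_volume):
        vol, mask, sp = uniform_volume
        with pytest.raises(ValueError, match="mismatch"):
            peribronchial_roi(
                vol, mask, (30.0, 30.0, 30.0), 20.0, sp, reference_tissue_ml=500.0
            )


class TestDeltaH:
    def test_worked_value(self):
        assert delta_h((0, 0, 60.0), (0, 0, 75.0), 200.0) == pytest.approx(0.075)

    def test_coincident_and_antisymmetric(self):
        a, s = (1.0, 2.0, 50.0), (3.0, 4.0, 42.0)
        assert delta_h(a, a, 180.0) == 0.0
        assert delta_h(a, s, 180.0) == -delta_h(s, a, 180.0)

    def test_requires_positive_height(self):
        with pytest.raises(ValueError):
            delta_h((0, 0, 0), (0, 0, 1), 0.0)
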