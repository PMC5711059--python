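"""Delivery simulator: aperture rasterization, the frame flip mechanism,
accumulation invariants and detector resampling."""

import numpy as np
import pytest

import arcqa
from arcqa.delivery import DeliveryConfig, _window_kernel

from conftest import asymmetric_control_point


def closed_control_point(n_pairs=40):
    z = np.zeros(n_pairs)
    return arcqa.ControlPoint(0, 0.0, 1.0, z, z)


def single_pair_control_point(a, b, pair=20, n_pairs=40, angle=0.0):
    av = np.zeros(n_pairs)
    bv = np.zeros(n_pairs)
    av[pair] = a
    bv[pair] = b
    return arcqa.ControlPoint(0, angle, 1.0, av, bv)


class TestRasterizeAperture:
    def test_all_closed_gives_zero_map(self):
        grid = arcqa.GridSpec(0.1, 5.0)
        dose = arcqa.rasterize_aperture(closed_control_point(), grid)
        assert np.all(dose.values == 0)

    def test_single_pair_integral_is_aperture_area(self):
        grid = arcqa.GridSpec(0.05, 13.5)
        cp = single_pair_control_point(-3.0, 2.0)
        dose = arcqa.rasterize_aperture(cp, grid)
        # 5 cm opening x 1 cm leaf band, partial-area weighting is exact
        assert dose.integral_cm2 == pytest.approx(5.0, abs=0.05 ** 2)

    def test_opening_bank_a_adds_area(self):
        grid = arcqa.GridSpec(0.05, 13.5)
        d0 = arcqa.rasterize_aperture(single_pair_control_point(-3.0, 2.0),
                                      grid)
        d1 = arcqa.rasterize_aperture(single_pair_control_point(-3.1, 2.0),
                                      grid)
        assert d1.integral_cm2 - d0.integral_cm2 == pytest.approx(0.1,
                                                                  rel=1e-9)

    def test_unit_intensity_inside_aperture(self):
        grid = arcqa.GridSpec(0.1, 13.5)
        dose = arcqa.rasterize_aperture(single_pair_control_point(-3.0, 2.0),
                                        grid)
        x = grid.coords
        ix = np.argmin(np.abs(x - 0.5))
        iy = np.argmin(np.abs(x - 0.5))  # pair 20 band is y in [0, 1]
        assert dose.values[iy, ix] == 1.0

    def test_aperture_outside_grid_raises_extent_error(self):
        grid = arcqa.GridSpec(0.1, 2.0)
        cp = single_pair_control_point(10.0, 11.0, pair=20)
        # x interval [10, 11] misses the +/-2 cm grid entirely
        with pytest.raises(arcqa.ExtentError):
            arcqa.rasterize_aperture(cp, grid)


class TestFrameTransform:
    @pytest.mark.parametrize("frame", ["GS", "CS"])
    def test_zero_angle_identity(self, frame):
        grid = arcqa.GridSpec(0.1, 5.0)
        fl = arcqa.rasterize_aperture(
            asymmetric_control_point(), grid)
        out = arcqa.frame_transform(fl, 0.0, frame)
        assert np.array_equal(out.values, fl.values)

    @pytest.mark.parametrize("angle", [-170.0, -90.0, 45.0, 90.0, 180.0])
    def test_gs_identity_at_any_angle(self, angle):
        grid = arcqa.GridSpec(0.1, 5.0)
        fl = arcqa.rasterize_aperture(asymmetric_control_point(), grid)
        out = arcqa.frame_transform(fl, angle, "GS")
        assert np.array_equal(out.values, fl.values)

    def test_cs_mirrors_beyond_ninety(self):
        grid = arcqa.GridSpec(0.1, 5.0)
        fl = arcqa.rasterize_aperture(asymmetric_control_point(), grid)
        out = arcqa.frame_transform(fl, 180.0, "CS")
        assert np.array_equal(out.values, fl.values[:, ::-1])
        assert not np.array_equal(out.values, fl.values)  # asymmetric
        near = arcqa.frame_transform(fl, 89.9, "CS")
        assert np.array_equal(near.values, fl.values)
        boundary = arcqa.frame_transform(fl, 90.0, "CS")
        assert np.array_equal(boundary.values, fl.values[:, ::-1])

    def test_angle_out_of_domain(self):
        grid = arcqa.GridSpec(0.1, 5.0)
        fl = arcqa.rasterize_aperture(asymmetric_control_point(), grid)
        with pytest.raises(ValueError):
            arcqa.frame_transform(fl, 200.0, "CS")


class TestAccumulateDose:
    def test_collapsed_plan_frames_identical(self, seeded_plan, coarse_grid):
        collapsed = arcqa.collapse_gantry(seeded_plan)
        gs = arcqa.accumulate_dose(collapsed, "GS", coarse_grid)
        cs = arcqa.accumulate_dose(collapsed, "CS", coarse_grid)
        assert np.array_equal(gs.values, cs.values)

    @pytest.mark.parametrize("sigma", [0.0, 0.3])
    def test_total_fluence_conserved_between_frames(self, seeded_plan,
                                                    coarse_grid, sigma):
        cfg = DeliveryConfig(penumbra_sigma_cm=sigma)
        gs = arcqa.accumulate_dose(seeded_plan, "GS", coarse_grid, cfg)
        cs = arcqa.accumulate_dose(seeded_plan, "CS", coarse_grid, cfg)
        rel = abs(gs.values.sum() - cs.values.sum()) / gs.values.sum()
        assert rel < 1e-9

    def test_single_symmetric_cp_at_zero(self):
        grid = arcqa.GridSpec(0.1, 13.5)
        cp = single_pair_control_point(-2.0, 2.0)
        plan = arcqa.ArcPlan("sym", [cp], delivery_mode="collapsed")
        cfg = DeliveryConfig(penumbra_sigma_cm=0.0)
        gs = arcqa.accumulate_dose(plan, "GS", grid, cfg)
        cs = arcqa.accumulate_dose(plan, "CS", grid, cfg)
        assert np.array_equal(gs.values, cs.values)
        assert np.allclose(gs.values, gs.values[:, ::-1])

    def test_penumbra_blur_conserves_integral(self, seeded_plan,
                                              coarse_grid):
        sharp = arcqa.accumulate_dose(seeded_plan, "GS", coarse_grid,
                                      DeliveryConfig(penumbra_sigma_cm=0.0))
        soft = arcqa.apply_penumbra(sharp, 0.3)
        assert soft.integral_cm2 == pytest.approx(sharp.integral_cm2,
                                                  rel=1e-6)
        assert not np.array_equal(soft.values, sharp.values)

    def test_cos_weighting_reduces_lateral_contribution(self, seeded_plan,
                                                        coarse_grid):
        uni = arcqa.accumulate_dose(seeded_plan, "GS", coarse_grid,
                                    DeliveryConfig(penumbra_sigma_cm=0.0))
        cos = arcqa.accumulate_dose(
            seeded_plan, "GS", coarse_grid,
            DeliveryConfig(penumbra_sigma_cm=0.0, weighting="cos"))
        assert cos.values.sum() < uni.values.sum()


class TestResample:
    def test_uniform_dose_stays_uniform(self):
        grid = arcqa.GridSpec(0.05, 13.5)
        dose = arcqa.PlanarDose(grid, np.full((grid.n_nodes,) * 2, 2.5),
                                frame="GS")
        for name in ("array729", "epid"):
            out = arcqa.resample_to_detector(dose,
                                             arcqa.DETECTOR_PRESETS[name])
            assert np.allclose(out.values, 2.5)

    def test_array_preset_covers_27x27_elements(self):
        grid = arcqa.GridSpec(0.05, 13.5)
        dose = arcqa.PlanarDose(grid, np.ones((grid.n_nodes,) * 2),
                                frame="GS")
        out = arcqa.resample_to_detector(dose,
                                         arcqa.DETECTOR_PRESETS["array729"])
        assert out.values.shape == (27, 27)
        assert out.grid.spacing_cm == 1.0

    def test_step_edge_bracketed_by_adjacent_elements(self):
        grid = arcqa.GridSpec(0.05, 13.5)
        values = np.where(grid.coords[None, :] < 0.5, 0.0, 1.0)
        dose = arcqa.PlanarDose(grid,
                                np.broadcast_to(values,
                                                (grid.n_nodes,) * 2).copy(),
                                frame="GS")
        out = arcqa.resample_to_detector(dose,
                                         arcqa.DETECTOR_PRESETS["array729"])
        xi = np.flatnonzero(out.grid.coords == 0.0)[0]
        left, right = out.values[13, xi], out.values[13, xi + 1]
        assert left < 0.5 < right

    def test_area_average_requires_fine_dose_grid(self):
        grid = arcqa.GridSpec(0.3, 13.5)
        dose = arcqa.PlanarDose(grid, np.ones((grid.n_nodes,) * 2),
                                frame="GS")
        det = arcqa.DetectorSpec("fine", 0.3, 0.1, "area-average")
        with pytest.raises(ValueError, match="pitch"):
            arcqa.resample_to_detector(dose, det)

    def test_lattice_exceeding_grid_raises(self):
        grid = arcqa.GridSpec(0.1, 5.0)
        dose = arcqa.PlanarDose(grid, np.ones((grid.n_nodes,) * 2),
                                frame="GS")
        det = arcqa.DetectorSpec("huge", 40.0, 12.0, "area-average")
        with pytest.raises(arcqa.ExtentError):
            arcqa.resample_to_detector(dose, det)

    def test_window_kernel_is_normalized_partition(self):
        for size, spacing in [(0.3, 0.05), (0.5, 0.05), (1.0, 0.3),
                              (0.3, 0.3)]:
            k = _window_kernel(size, spacing)
            assert k.sum() == pytest.approx(1.0)
            assert np.all(k >= 0)

    def test_analysis_downsample_preserves_mean(self, seeded_plan):
        fine = arcqa.accumulate_dose(
            seeded_plan, "GS", arcqa.GridSpec(0.05, 13.5),
            DeliveryConfig(penumbra_sigma_cm=0.3))
        coarse = arcqa.resample_to_grid(fine, 0.3)
        # block mean of a smooth map preserves the central plateau level
        n = fine.grid.n_nodes // 2
        m = coarse.grid.n_nodes // 2
        assert coarse.values[m, m] == pytest.approx(fine.values[n, n],
                                                    rel=0.2)
        assert coarse.values.sum() * coarse.grid.cell_area_cm2 == \
            pytest.approx(fine.integral_cm2, rel=0.05)
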