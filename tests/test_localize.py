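"""ODR axis fitting, endpoint extraction, tip disambiguation, the no-2D
baseline, and full-pipeline orchestration."""

import numpy as np
import pytest

from needlepipe import (AxisAmbiguousError, ClassicalPlanarBackend,
                        ClassicalVolumetricBackend, CorridorEmptyError,
                        DegenerateMaskError, Mask2D, Mask3D,
                        MaskResamplePlanarBackend, NeedleLocalization,
                        PhantomSpec, PlaneFrame, PrecomputedVolumetricBackend,
                        StageError, Volume3D, VolumeGrid, axis_error,
                        disambiguate_tip, extract_endpoints, fit_axis_odr,
                        generate_phantom, localize_no2d, perturb_mask,
                        run_pipeline, small_grid, tip_error)
from needlepipe.errors import NeedlePipeError, SegmentationEmptyError
from needlepipe.localize import Line2D, PipelineConfig
from conftest import truth_localization


def brute_force_odr_residual(points):
    """Independent oracle: scan line angles on a 0.01-degree grid (with a
    fine local refinement at the best angle) and return the minimal
    orthogonal residual sum over lines through the centroid."""
    pts = np.asarray(points, float)
    rel = pts - pts.mean(axis=0)
    total = float(np.einsum("ij,ij->i", rel, rel).sum())

    def residuals(angles):
        d = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        return total - ((rel @ d.T) ** 2).sum(axis=0)

    coarse = np.deg2rad(np.arange(0.0, 180.0, 0.01))
    r = residuals(coarse)
    best = coarse[int(np.argmin(r))]
    fine = best + np.deg2rad(np.linspace(-0.01, 0.01, 1001))
    return float(residuals(fine).min())


class TestOdrFit:
    def test_exact_collinear_points(self):
        line = fit_axis_odr([(0, 0), (1, 1), (2, 2)])
        assert np.allclose(np.abs(line.direction), 1 / np.sqrt(2), atol=1e-12)
        assert brute_force_odr_residual([(0, 0), (1, 1), (2, 2)]) < 1e-12

    def test_rectangle_corners_align_with_long_side(self):
        line = fit_axis_odr([(0, 0), (10, 0), (0, 2), (10, 2)])
        assert np.allclose(line.direction, (1, 0), atol=1e-12)

    def test_noisy_points_match_brute_force_scan(self):
        rng = np.random.default_rng(8)
        t = rng.uniform(0, 50, size=200)
        d = np.array([np.cos(0.4), np.sin(0.4)])
        pts = np.array([3.0, -2.0]) + t[:, None] * d + rng.normal(0, 0.5, (200, 2))
        line = fit_axis_odr(pts)
        res = sum((np.linalg.norm(p - line.point)**2 - ((p - line.point) @ line.direction)**2)
                  for p in pts)
        oracle = brute_force_odr_residual(pts)
        assert res == pytest.approx(oracle, rel=1e-6)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateMaskError):
            fit_axis_odr([(1, 1), (1, 1), (1, 1)])
        square = [(0, 0), (0, 1), (1, 0), (1, 1)]
        with pytest.raises(AxisAmbiguousError):
            fit_axis_odr(square)


def bar_mask(frame, i0, i1, j0, j1):
    data = np.zeros(frame.size, dtype=np.uint8)
    data[i0:i1, j0:j1] = 1
    return Mask2D(frame=frame, data=data)


def simple_frame(size=(60, 20), origin=(0, 0, 0)):
    return PlaneFrame(origin=origin, u_axis=(1, 0, 0), v_axis=(0, 1, 0),
                      pixel_spacing=(1.0, 1.0), size=size)


class TestEndpoints:
    def test_horizontal_bar_endpoints_on_fitted_line(self):
        frame = simple_frame()
        mask = bar_mask(frame, 0, 51, 5, 8)  # s in [0, 50], 3 px wide
        line = fit_axis_odr(np.argwhere(mask.data > 0).astype(float))
        a, b = extract_endpoints(mask, line, corridor_halfwidth_mm=3.0)
        assert a[0] == pytest.approx(0.0, abs=1e-9)
        assert b[0] == pytest.approx(50.0, abs=1e-9)
        assert a[1] == b[1] == pytest.approx(6.0, abs=1e-9)  # on the axis
        # canonical order: smaller projection first
        assert (a @ line.direction) < (b @ line.direction)

    def test_empty_corridor_raises(self):
        frame = simple_frame()
        mask = bar_mask(frame, 10, 40, 5, 8)
        far_line = Line2D(point=(25.0, 15.0), direction=(1.0, 0.0))
        with pytest.raises(CorridorEmptyError):
            extract_endpoints(mask, far_line, corridor_halfwidth_mm=2.0)


class TestDisambiguation:
    def test_deep_endpoint_is_tip(self):
        grid = VolumeGrid(shape=(100, 100, 100), spacing=(1, 1, 1), origin=(0, 0, 0))
        frame = simple_frame(origin=(0, 50, 50))
        # endpoint at s=5 is 5 mm from the x=0 face; s=60 is deep
        tip2d, entry2d = disambiguate_tip(np.array([5.0, 0.0]), np.array([60.0, 0.0]),
                                          frame, grid)
        assert tip2d[0] == 60.0
        assert entry2d[0] == 5.0

    def test_tie_prefers_inferior_entry(self, caplog):
        grid = VolumeGrid(shape=(100, 100, 100), spacing=(1, 1, 1), origin=(0, 0, 0))
        frame = PlaneFrame(origin=(49.5, 50, 30), u_axis=(0, 0, 1), v_axis=(0, 1, 0),
                           pixel_spacing=(1, 1), size=(40, 40))
        # both endpoints 30 mm from the nearest face, one superior one inferior
        with caplog.at_level("WARNING"):
            tip2d, entry2d = disambiguate_tip(np.array([0.0, 0.0]),
                                              np.array([39.0, 0.0]), frame, grid)
        assert tip2d[0] == 39.0  # superior endpoint becomes the tip
        assert any("equidistant" in r.message for r in caplog.records)

    def test_manual_rule_overrides_boundary(self):
        grid = VolumeGrid(shape=(100, 100, 100), spacing=(1, 1, 1), origin=(0, 0, 0))
        frame = simple_frame(origin=(0, 50, 50))
        tip2d, _ = disambiguate_tip(np.array([5.0, 0.0]), np.array([60.0, 0.0]),
                                    frame, grid, tip_rule=("manual", (-1, 0, 0)))
        assert tip2d[0] == 5.0

    def test_recovers_generator_tip_label_across_sampled_specs(self, small_specs):
        for spec in small_specs:
            _, truth = generate_phantom(spec)
            loc = localize_no2d(truth.mask)
            assert np.linalg.norm(loc.tip - truth.tip) < \
                np.linalg.norm(loc.tip - truth.entry)


class TestNo2dBaseline:
    def test_cylinder_length_recovered_within_voxel_diagonal(self):
        spec = PhantomSpec(grid=small_grid(), entry_point=(20.0, 30.0, 80.0),
                           insertion_depth=60.0, angle_to_axial_deg=-40.0,
                           azimuth_deg=25.0, noise_sd=0.0, seed=5)
        _, truth = generate_phantom(spec)
        loc = localize_no2d(truth.mask)
        length = np.linalg.norm(loc.tip - loc.entry)
        diag = np.linalg.norm(spec.grid.spacing)
        assert 60.0 - diag <= length <= 60.0 + diag

    def test_tip_oversegmentation_biases_no2d_more_than_full_pipeline(self):
        """A spherical over-segmentation cap at the tip drags the no-2D tip
        beyond the truth, while the 2D stage re-segments the clean image."""
        spec = PhantomSpec(grid=small_grid(), entry_point=(20.0, 30.0, 80.0),
                           insertion_depth=55.0, angle_to_axial_deg=-35.0,
                           azimuth_deg=40.0, seed=9)
        vol, truth = generate_phantom(spec)
        ref = truth_localization(truth)
        cap_radius = 8.0
        perturbed = perturb_mask(truth.mask, "tip_oversegment", cap_radius, seed=1)
        err_no2d = tip_error(localize_no2d(perturbed), ref)
        loc_full, _ = run_pipeline(vol, PrecomputedVolumetricBackend(perturbed),
                                   ClassicalPlanarBackend())
        err_full = tip_error(loc_full, ref)
        assert err_no2d >= cap_radius - 2.0
        assert err_full < err_no2d

    def test_output_independent_of_voxel_enumeration(self):
        spec = PhantomSpec(grid=small_grid(), entry_point=(20.0, 30.0, 80.0),
                           insertion_depth=50.0, angle_to_axial_deg=-45.0,
                           azimuth_deg=10.0, noise_sd=0.0, seed=2)
        _, truth = generate_phantom(spec)
        a = localize_no2d(truth.mask)
        b = localize_no2d(Mask3D(grid=truth.mask.grid, data=truth.mask.data.copy()))
        assert np.array_equal(a.tip, b.tip) and np.array_equal(a.entry, b.entry)


class TestPipeline:
    def test_classical_recovery_on_phantom(self, small_specs):
        spec = small_specs[1]
        vol, truth = generate_phantom(spec)
        loc, inter = run_pipeline(vol, ClassicalVolumetricBackend(),
                                  ClassicalPlanarBackend())
        assert tip_error(loc, truth_localization(truth)) <= 2.0
        assert axis_error(loc.axis_direction, truth.axis_direction) <= 1.5
        assert loc.provenance == "full_pipeline"
        assert inter.frame is not None and inter.mask2d is not None

    def test_truth_injection_recovers_within_one_pixel(self, small_specs):
        spec = small_specs[2]
        vol, truth = generate_phantom(spec)
        loc, _ = run_pipeline(vol, PrecomputedVolumetricBackend(truth.mask),
                              MaskResamplePlanarBackend(truth.mask))
        assert tip_error(loc, truth_localization(truth)) <= 1.35

    def test_deterministic_outputs(self, small_specs):
        spec = small_specs[3]
        vol, truth = generate_phantom(spec)
        a, _ = run_pipeline(vol, ClassicalVolumetricBackend(), ClassicalPlanarBackend())
        b, _ = run_pipeline(vol, ClassicalVolumetricBackend(), ClassicalPlanarBackend())
        assert np.array_equal(a.tip, b.tip)
        assert np.array_equal(a.entry, b.entry)

    def test_no2d_flag_switches_variant(self, small_specs):
        vol, truth = generate_phantom(small_specs[4])
        loc, inter = run_pipeline(vol, ClassicalVolumetricBackend(), None,
                                  PipelineConfig(no_2d=True))
        assert loc.provenance == "no_2d_baseline"
        assert inter.frame is None

    def test_needle_not_detected_names_stage(self):
        grid = small_grid()
        vol = Volume3D(grid=grid, data=np.full(grid.shape, 50.0))
        with pytest.raises(StageError, match="step1-segmentation") as exc:
            run_pipeline(vol, ClassicalVolumetricBackend(), ClassicalPlanarBackend())
        assert "needle not detected" in str(exc.value)

    def test_empty_2d_segmentation_falls_back_to_no2d(self, small_specs, caplog):
        class EmptyPlanar:
            kind, descriptor = "planar", "always-empty"

            def predict(self, image):
                raise SegmentationEmptyError("nothing found")

        vol, truth = generate_phantom(small_specs[5])
        with caplog.at_level("WARNING"):
            loc, inter = run_pipeline(vol, ClassicalVolumetricBackend(), EmptyPlanar())
        assert loc.provenance == "no_2d_baseline"
        assert "step3-segmentation-empty-fallback-no2d" in inter.stage_log

    def test_localization_invariants_enforced(self):
        with pytest.raises(NeedlePipeError):
            NeedleLocalization(tip=(1, 1, 1), entry=(1, 1, 1), axis_direction=(1, 0, 0))
        with pytest.raises(NeedlePipeError):
            NeedleLocalization(tip=(1, 0, 0), entry=(0, 0, 0), axis_direction=(0, 1, 0))

    def test_lifted_endpoints_lie_on_plane_and_inside_volume(self, small_specs):
        vol, truth = generate_phantom(small_specs[0])
        loc, inter = run_pipeline(vol, ClassicalVolumetricBackend(),
                                  ClassicalPlanarBackend())
        from needlepipe import world_to_plane
        for p in (loc.tip, loc.entry):
            _, dist = world_to_plane(p, inter.frame)
            assert abs(dist) < 1e-9
            assert vol.grid.contains_world(p)
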