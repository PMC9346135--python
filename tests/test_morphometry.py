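import numpy as np
import pytest

from choroidref import (
    BoundaryCurves,
    OctVolume,
    ScanGeometry,
    measure_eye,
)
from choroidref.morphometry import (
    AREA_NAMES,
    THICKNESS_NAMES,
    MeasureConfig,
    MeasurementSpanError,
    _nearest_bscan,
    area_between,
    landmark_positions_um,
    measure_landmarks,
    nasal_sign,
    thickness_at,
)
from choroidref.nulla import NullaPoint

from conftest import make_constant_boundaries
from oracles import dense_area


class TestThicknessAt:
    def test_scale_arithmetic(self, geometry):
        """50 choroid pixels at the default axial scale are
        50 x (1900/496) = 191.53 um."""
        shape = (geometry.n_bscans, geometry.width_px)
        curves = BoundaryCurves(
            ilm=np.full(shape, 200.0),
            choroid_inner=np.full(shape, 380.0),
            choroid_outer=np.full(shape, 430.0),
        )
        t = thickness_at(curves, 0, 1000.0, geometry)
        assert t == pytest.approx(50 * 1900 / 496)
        assert t == pytest.approx(191.53, abs=0.01)

    def test_constant_boundaries_any_fractional_x(self, geometry):
        curves = make_constant_boundaries(geometry, thickness_um=193.0)
        for x in (0.0, 123.456, 2650.0, 5280.1):
            assert thickness_at(curves, 3, x, geometry) == pytest.approx(193.0)

    def test_linear_ramp_midpoint_is_mean(self, geometry):
        """On a linear boundary ramp, thickness halfway between two pixels
        equals the mean of the two pixel thicknesses."""
        shape = (1, geometry.width_px)
        ramp = np.linspace(400, 450, geometry.width_px)
        curves = BoundaryCurves(
            ilm=np.zeros(shape),
            choroid_inner=np.full(shape, 380.0),
            choroid_outer=ramp[None, :],
        )
        s = geometry.lateral_scale
        mid = thickness_at(curves, 0, 100.5 * s, geometry)
        t100 = thickness_at(curves, 0, 100 * s, geometry)
        t101 = thickness_at(curves, 0, 101 * s, geometry)
        assert mid == pytest.approx((t100 + t101) / 2, rel=1e-12)

    def test_outside_scan_rejected(self, geometry):
        curves = make_constant_boundaries(geometry)
        with pytest.raises(MeasurementSpanError):
            thickness_at(curves, 0, -5.0, geometry)
        with pytest.raises(MeasurementSpanError):
            thickness_at(curves, 0, 6000.0, geometry)


class TestLandmarks:
    def test_constant_profile_all_landmarks_equal(self, geometry):
        curves = make_constant_boundaries(geometry, thickness_um=193.0)
        nulla = NullaPoint(bscan=12, lateral=256.0, depth=90.0)
        t = measure_landmarks(curves, nulla, "OD", geometry)
        assert np.allclose(t, 193.0)

    def test_ordering_nasal_to_temporal(self, geometry):
        positions = landmark_positions_um(2650.0, "OD")
        assert positions[0] == 2650.0 + 2000.0  # T1 most nasal (+x for OD)
        assert positions[4] == 2650.0  # T5 at the nulla
        assert positions[8] == 2650.0 - 2000.0
        flipped = landmark_positions_um(2650.0, "OS")
        assert np.allclose(flipped, 2 * 2650.0 - positions)

    def test_landmark_outside_scan_names_landmark(self, geometry):
        curves = make_constant_boundaries(geometry)
        nulla = NullaPoint(bscan=12, lateral=10.0, depth=90.0)  # near edge
        with pytest.raises(MeasurementSpanError, match="T"):
            measure_landmarks(curves, nulla, "OD", geometry)

    def test_nasal_sign_convention(self):
        assert nasal_sign("OD") == 1
        assert nasal_sign("OS") == -1
        assert nasal_sign("OD", "nasal_positive_os") == -1


class TestAreaBetween:
    def test_rectangles(self, geometry):
        """Constant 193 um thickness: 500 um span -> 96,500 um^2 and a
        100 um umbo span -> 19,300 um^2."""
        curves = make_constant_boundaries(geometry, thickness_um=193.0)
        assert area_between(curves, 0, 1000.0, 1500.0, geometry) == \
            pytest.approx(96_500.0, rel=1e-12)
        assert area_between(curves, 0, 2600.0, 2700.0, geometry) == \
            pytest.approx(19_300.0, rel=1e-12)

    def test_matches_dense_quadrature(self, geometry):
        rng = np.random.default_rng(8)
        shape = (1, geometry.width_px)
        x = np.arange(geometry.width_px)
        outer = 400 + 20 * np.sin(x / 30) + rng.normal(0, 1, geometry.width_px)
        curves = BoundaryCurves(
            ilm=np.zeros(shape),
            choroid_inner=np.full(shape, 350.0),
            choroid_outer=outer[None, :],
        )
        a = area_between(curves, 0, 433.3, 2987.1, geometry)
        oracle = dense_area(
            lambda xu: thickness_at(curves, 0, xu, geometry), 433.3, 2987.1,
            n=1000)
        assert a == pytest.approx(oracle, rel=0.005)

    def test_inverted_interval_rejected(self, geometry):
        curves = make_constant_boundaries(geometry)
        with pytest.raises(MeasurementSpanError):
            area_between(curves, 0, 1500.0, 1000.0, geometry)


class TestScaleCovariance:
    def test_axial_scale_doubles_thickness_and_area(self):
        g1 = ScanGeometry(width_px=64, depth_px=64, n_bscans=3,
                          width_um=640, depth_um=640, bscan_spacing_um=10)
        g2 = ScanGeometry(width_px=64, depth_px=64, n_bscans=3,
                          width_um=640, depth_um=1280, bscan_spacing_um=10)
        curves = BoundaryCurves(
            ilm=np.zeros((3, 64)),
            choroid_inner=np.full((3, 64), 20.0),
            choroid_outer=np.full((3, 64), 40.0),
        )
        assert thickness_at(curves, 0, 100.0, g2) == \
            pytest.approx(2 * thickness_at(curves, 0, 100.0, g1))
        assert area_between(curves, 0, 50.0, 150.0, g2) == \
            pytest.approx(2 * area_between(curves, 0, 50.0, 150.0, g1))

    def test_lateral_scale_doubles_area_only(self):
        g1 = ScanGeometry(width_px=64, depth_px=64, n_bscans=3,
                          width_um=640, depth_um=640, bscan_spacing_um=10)
        g2 = ScanGeometry(width_px=64, depth_px=64, n_bscans=3,
                          width_um=1280, depth_um=640, bscan_spacing_um=10)
        curves = BoundaryCurves(
            ilm=np.zeros((3, 64)),
            choroid_inner=np.full((3, 64), 20.0),
            choroid_outer=np.full((3, 64), 40.0),
        )
        assert thickness_at(curves, 0, 100.0, g2) == \
            pytest.approx(thickness_at(curves, 0, 100.0, g1))
        # Same pixel interval in each geometry: twice the um span.
        a1 = area_between(curves, 0, 100.0, 300.0, g1)
        a2 = area_between(curves, 0, 200.0, 600.0, g2)
        assert a2 == pytest.approx(2 * a1)


class TestMeasureEye:
    def test_parameter_counts(self, small_eye):
        """17 grid parameters and a 5-member nulla sub-analysis."""
        volume, masks, _ = small_eye
        m = measure_eye(volume, masks)
        assert len(m.grid_parameters) == 17
        assert len(m.nulla_subanalysis) == 5
        assert set(m.nulla_subanalysis) == {"T5", "TUn", "TUt", "AUn", "AUt"}

    def test_recovers_generator_truth(self, small_geometry, small_eye):
        """Full pipeline recovers all 21 closed-form landmark values within
        the rasterization bound: 2 axial px for thicknesses, 2 axial px
        times the span for areas."""
        volume, masks, truth = small_eye
        m = measure_eye(volume, masks)
        tol_um = 2 * small_geometry.axial_scale
        t = truth.true_measurements
        for i, name in enumerate(THICKNESS_NAMES):
            assert abs(m.thicknesses_um[i] - t[name]) < tol_um, name
        for i, name in enumerate(AREA_NAMES):
            assert abs(m.areas_um2[i] - t[name]) < tol_um * 500.0, name
        assert abs(m.umbo_thicknesses_um[0] - t["TUn"]) < tol_um
        assert abs(m.umbo_thicknesses_um[1] - t["TUt"]) < tol_um
        assert abs(m.umbo_areas_um2[0] - t["AUn"]) < tol_um * 100.0
        assert abs(m.umbo_areas_um2[1] - t["AUt"]) < tol_um * 100.0

    def test_recovers_truth_at_default_geometry(self, geometry,
                                                small_eye_params):
        """At the full-resolution scan geometry the recovery is tighter:
        thicknesses within 2 axial px (~7.7 um) and areas within 2%."""
        import dataclasses

        from choroidref import generate_eye

        params = dataclasses.replace(small_eye_params, pit_bscan=12)
        volume, masks, truth = generate_eye(geometry, params, seed=11,
                                            render_intensity=False)
        m = measure_eye(volume, masks)
        t = truth.true_measurements
        tol_um = 2 * geometry.axial_scale
        for i, name in enumerate(THICKNESS_NAMES):
            assert abs(m.thicknesses_um[i] - t[name]) < tol_um, name
        for i, name in enumerate(AREA_NAMES):
            assert abs(m.areas_um2[i] - t[name]) / t[name] < 0.02, name
        assert abs(m.umbo_areas_um2[0] - t["AUn"]) / t["AUn"] < 0.02
        assert abs(m.umbo_areas_um2[1] - t["AUt"]) / t["AUt"] < 0.02

    def test_area_additivity(self, small_geometry, small_eye):
        """Sum of A1..A8 equals the area over the full +/-2000 um span."""
        volume, masks, _ = small_eye
        m = measure_eye(volume, masks)
        from choroidref import extract_boundaries

        curves = extract_boundaries(masks)
        lo = m.nulla_x_um - 2000.0
        hi = m.nulla_x_um + 2000.0
        full = area_between(curves, m.nulla_bscan, lo, hi, small_geometry)
        assert m.areas_um2.sum() == pytest.approx(full, rel=1e-6)

    def test_od_os_mirror_swap(self, small_geometry, small_eye):
        """A laterally mirrored volume measured as the fellow eye side gives
        numerically identical named measurements."""
        volume, masks, _ = small_eye
        m_od = measure_eye(volume, masks)
        mirrored = OctVolume(
            bscans=volume.bscans[:, :, ::-1],
            geometry=small_geometry,
            quality=volume.quality,
            eye_id="mirror", side="OS",
            sex=volume.sex, origin=volume.origin,
        )
        m_os = measure_eye(mirrored, masks[:, :, ::-1])
        assert np.allclose(m_os.thicknesses_um, m_od.thicknesses_um, rtol=1e-9)
        assert np.allclose(m_os.areas_um2, m_od.areas_um2, rtol=1e-9)
        assert m_os.umbo_thicknesses_um == pytest.approx(
            m_od.umbo_thicknesses_um, rel=1e-9)

    def test_errors_annotated_with_eye_id(self, small_geometry, small_eye):
        volume, masks, _ = small_eye
        bad = masks.copy()
        bad[0, :, 0][bad[0, :, 0] == 3] = 0  # remove choroid from one column
        from choroidref import BoundaryExtractionError

        with pytest.raises(BoundaryExtractionError, match=volume.eye_id):
            measure_eye(volume, bad)


@pytest.mark.parametrize(
    "coord, n, expected",
    [(11.4, 25, 11), (11.6, 25, 12), (12.0, 25, 12),
     (11.5, 25, 12), (12.5, 25, 12)],  # half-way ties resolve toward centre
)
def test_nearest_bscan_tie_rule(coord, n, expected):
    assert _nearest_bscan(coord, n) == expected
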