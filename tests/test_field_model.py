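"""Field-model tests: solver correctness, analytic oracle, zone areas."""

from __future__ import annotations

import math

import numpy as np
import pytest

import tuberfield as tf
from tuberfield.field_model import (
    ConvergenceError,
    analytic_midgap_magnitude,
    analytic_two_wire,
    export_contours_csv,
    export_field_map,
)


def _offgrid_selection(grid, config, min_dist_mm):
    """Nodes at least ``min_dist_mm`` from either electrode surface."""
    X, Y = grid.mesh()
    c = config.center_spacing_d / 2
    a = config.radius_a
    dist = np.minimum(np.hypot(X - c, Y), np.hypot(X + c, Y)) - a
    return X, Y, dist >= min_dist_mm


class TestAnalyticTwoWire:
    def test_midpoint_is_half_voltage(self, config_1000):
        phi = analytic_two_wire(config_1000, [(0.0, 0.0)])
        assert phi[0] == pytest.approx(500.0, abs=1e-9)

    def test_electrode_surface_is_equipotential(self, config_1000):
        c = config_1000.center_spacing_d / 2
        a = config_1000.radius_a
        angles = np.linspace(0, 2 * np.pi, 37)
        pts = np.column_stack([c + a * np.cos(angles), a * np.sin(angles)])
        phi = analytic_two_wire(config_1000, pts)
        assert np.abs(phi - 1000.0).max() <= 1e-9 * 1000.0

    def test_point_inside_electrode_rejected(self, config_1000):
        with pytest.raises(ValueError):
            analytic_two_wire(config_1000, [(5.0, 0.0)])

    def test_midgap_magnitude_against_numerical_gradient(self, config_1000):
        """The closed-form midgap |E| must agree with central differencing
        of the analytic potential itself (the self-consistency check that
        validates the oracle before it is trusted)."""
        eps = 1e-5
        phi = analytic_two_wire(config_1000, [(-eps, 0.0), (eps, 0.0)])
        e_numeric_v_per_cm = abs(phi[1] - phi[0]) / (2 * eps) * 10.0
        e_closed = analytic_midgap_magnitude(config_1000)
        assert e_closed == pytest.approx(e_numeric_v_per_cm, rel=1e-6)
        # order of magnitude: ~6.7e2 V/cm for a=0.5, d=10, V0=1000
        assert 600.0 < e_closed < 750.0


class TestSolveLaplace:
    def test_zero_voltage_gives_zero_potential(self, coarse_grid):
        pf = tf.solve_laplace(tf.ElectrodeConfig(applied_voltage_V0=0.0),
                              coarse_grid)
        assert np.all(pf.phi == 0.0)

    def test_dirichlet_values_held_exactly(self, solved_coarse):
        X, Y = solved_coarse.grid.mesh()
        pos = (X - 5.0) ** 2 + Y**2 <= 0.25
        neg = (X + 5.0) ** 2 + Y**2 <= 0.25
        assert np.all(solved_coarse.phi[pos] == 1000.0)
        assert np.all(solved_coarse.phi[neg] == 0.0)

    def test_discrete_maximum_principle(self, solved_coarse):
        assert solved_coarse.phi.min() >= 0.0
        assert solved_coarse.phi.max() <= 1000.0

    def test_midpoint_potential_is_half_v0(self, solved_coarse):
        grid = solved_coarse.grid
        mid = solved_coarse.phi[grid.ny // 2, grid.nx // 2]
        assert mid == pytest.approx(500.0, rel=0.01)

    def test_mirror_symmetries_of_magnitude(self, solved_coarse):
        fm = tf.field_magnitude(solved_coarse)
        mag = fm.magnitude
        assert np.allclose(mag, mag[::-1, :], rtol=1e-8, atol=1e-6)
        assert np.allclose(mag, mag[:, ::-1], rtol=1e-8, atol=1e-6)

    def test_agrees_with_analytic_oracle_in_central_region(self, config_1000):
        """Away from both the electrode staircase and the insulating
        walls (which the unbounded-medium oracle does not model), the
        discrete solution tracks the closed form to ~1% of V0."""
        grid = tf.GridSpec(spacing_h=0.1)
        pf = tf.solve_laplace(config_1000, grid)
        X, Y, far = _offgrid_selection(grid, config_1000, 1.0)
        central = far & (np.hypot(X, Y) <= 10.0)
        pts = np.column_stack([X[central], Y[central]])
        ana = analytic_two_wire(config_1000, pts)
        max_err = np.abs(pf.phi[central] - ana).max() / 1000.0
        assert max_err <= 0.02

    def test_electrodes_overlapping_boundary_rejected(self, config_1000):
        small = tf.GridSpec(width=22.0, height=22.0, spacing_h=0.2)
        wide = tf.ElectrodeConfig(applied_voltage_V0=100.0, center_spacing_d=21.0,
                                  radius_a=0.5, exposure_length=10.0)
        with pytest.raises(ValueError):
            tf.solve_laplace(wide, small)

    def test_invalid_tolerance_rejected(self, config_1000, coarse_grid):
        with pytest.raises(ValueError):
            tf.solve_laplace(config_1000, coarse_grid, tol=0.0)

    def test_convergence_error_reports_residual(self):
        err = ConvergenceError(achieved=1e-3, tol=1e-6)
        assert "1.000e-03" in str(err) and "1.000e-06" in str(err)


class TestFieldMagnitude:
    def test_uniform_potential_gives_zero_field(self, coarse_grid):
        pf = tf.PotentialField(
            grid=coarse_grid,
            phi=np.full((coarse_grid.ny, coarse_grid.nx), 7.0),
            electrode_mask=np.zeros((coarse_grid.ny, coarse_grid.nx), bool),
            config=tf.ElectrodeConfig(applied_voltage_V0=7.0),
        )
        fm = tf.field_magnitude(pf)
        assert np.all(fm.magnitude == 0.0)

    def test_linear_potential_gives_exact_constant_field(self, coarse_grid):
        slope = 3.0  # V/mm
        X, _ = coarse_grid.mesh()
        pf = tf.PotentialField(
            grid=coarse_grid,
            phi=slope * X,
            electrode_mask=np.zeros_like(X, dtype=bool),
            config=tf.ElectrodeConfig(applied_voltage_V0=1.0),
        )
        fm = tf.field_magnitude(pf)
        # central differences are exact on a linear field; 10x converts to V/cm
        assert np.allclose(fm.magnitude, 10.0 * slope, rtol=1e-12)

    def test_voltage_linearity_of_magnitude(self, coarse_grid):
        fm1 = tf.field_magnitude(
            tf.solve_laplace(tf.ElectrodeConfig(applied_voltage_V0=500.0),
                             coarse_grid))
        fm2 = tf.field_magnitude(
            tf.solve_laplace(tf.ElectrodeConfig(applied_voltage_V0=1000.0),
                             coarse_grid))
        assert np.allclose(2.0 * fm1.magnitude, fm2.magnitude, rtol=1e-9,
                           atol=1e-9)


class TestIsocontourArea:
    def test_threshold_above_maximum_gives_empty_set(self, field_default_grid):
        area, polylines = tf.isocontour_area(
            field_default_grid, field_default_grid.magnitude.max() * 2
        )
        assert area == 0.0
        assert polylines == []

    def test_non_positive_threshold_rejected(self, field_default_grid):
        with pytest.raises(ValueError):
            tf.isocontour_area(field_default_grid, 0.0)

    def test_voltage_threshold_scaling_identity(self, field_default_grid):
        """A(s*t at s*V0) equals A(t at V0): super-level sets are invariant
        under joint scaling of drive and threshold."""
        for s in (0.5, 2.0):
            for t in (100.0, 250.0, 500.0):
                a_ref, _ = tf.isocontour_area(field_default_grid, t)
                scaled = field_default_grid.rescaled(1000.0 * s)
                a_scaled, _ = tf.isocontour_area(scaled, s * t)
                assert a_scaled == pytest.approx(a_ref, rel=0.02)

    def test_area_monotone_nonincreasing_in_threshold(self, field_default_grid):
        areas = [tf.isocontour_area(field_default_grid, t)[0]
                 for t in (100.0, 250.0, 500.0, 800.0)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_fine_grid_counting_oracle(self, field_fine):
        """Frozen reference: brute-force node counting at h = 0.025 mm
        (V0 = 300 V, threshold 100 V/cm, 60 x 60 mm domain, computed via
        a symmetry-reduced quarter-domain solve) gave 1.435169 cm^2; the
        h = 0.05 result must match within 2%."""
        reference_cm2 = 1.435169
        fm_300 = field_fine.rescaled(300.0)
        area, _ = tf.isocontour_area(fm_300, 100.0)
        assert area == pytest.approx(reference_cm2, rel=0.02)

    def test_grid_convergence_of_iso_areas(self, field_default_grid, field_fine):
        """Halving the default grid spacing (0.1 -> 0.05 mm) moves the
        iso-areas by less than 2% for thresholds in [100, 500] V/cm."""
        for t in (100.0, 250.0, 500.0):
            a_h, _ = tf.isocontour_area(field_default_grid, t)
            a_h2, _ = tf.isocontour_area(field_fine, t)
            assert a_h == pytest.approx(a_h2, rel=0.02)

    def test_polylines_are_in_mm_coordinates(self, field_default_grid):
        _, polylines = tf.isocontour_area(field_default_grid, 250.0)
        assert len(polylines) >= 1
        allpts = np.vstack(polylines)
        assert np.abs(allpts).max() <= 30.0  # inside the 60 mm domain


class TestPredictZones:
    def test_inverted_thresholds_rejected(self, field_default_grid):
        with pytest.raises(ValueError):
            tf.predict_zones(field_default_grid, ire_threshold=100.0,
                             re_threshold=250.0)

    def test_masks_disjoint_and_union_is_re_superlevel(self, field_default_grid):
        zones = tf.predict_zones(field_default_grid)
        assert not np.any(zones.ire_mask & zones.re_mask)
        expected = (field_default_grid.magnitude >= 100.0) & \
            ~field_default_grid.electrode_mask
        assert np.array_equal(zones.ire_mask | zones.re_mask, expected)

    def test_vanishing_band_has_vanishing_area(self, field_default_grid):
        zones = tf.predict_zones(field_default_grid, ire_threshold=250.0,
                                 re_threshold=249.999)
        assert zones.re_area <= 0.01

    def test_ire_area_grows_with_voltage(self, field_default_grid):
        low = tf.predict_zones(field_default_grid.rescaled(300.0))
        high = tf.predict_zones(field_default_grid.rescaled(1500.0))
        assert high.ire_area > low.ire_area


class TestExports:
    def test_field_map_roundtrip_with_sidecar(self, field_default_grid, tmp_path):
        from PIL import Image

        path = export_field_map(field_default_grid, tmp_path / "field.tif")
        back = np.asarray(Image.open(path))
        assert back.shape == field_default_grid.magnitude.shape
        assert np.allclose(back, field_default_grid.magnitude, rtol=1e-6)
        sidecar = (tmp_path / "field.hdr.txt").read_text()
        assert "V/cm" in sidecar and "0.1" in sidecar

    def test_contours_csv_layout(self, field_default_grid, tmp_path):
        _, polylines = tf.isocontour_area(field_default_grid, 250.0)
        path = export_contours_csv({250.0: polylines}, tmp_path / "c.csv")
        lines = path.read_text().splitlines()
        assert lines[0] == "threshold_vcm,contour_id,x_mm,y_mm"
        assert len(lines) > 10
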