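"""Unit and property tests for the TG-43 line-source dose engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tg43qa as q
from tg43qa.engine import DomainError


def geometry_oracle(r, theta_deg, L):
    """Independent subtended-angle construction via two arctangents."""
    th = math.radians(theta_deg)
    t1 = math.atan2(r * math.sin(th), r * math.cos(th) - L / 2)
    t2 = math.atan2(r * math.sin(th), r * math.cos(th) + L / 2)
    return (t1 - t2) / (L * r * math.sin(th))


class TestGeometryFactor:
    def test_on_axis_value(self):
        # 1/(r^2 - L^2/4) at r=1, L=0.5
        assert q.geometry_factor(1.0, 0.0, 0.5) == pytest.approx(1 / (1 - 0.0625))

    def test_point_source_limit_at_90(self):
        assert q.geometry_factor(2.0, 90.0, 1e-4) == pytest.approx(0.25, abs=1e-6)

    @pytest.mark.parametrize("r,theta,L", [
        (1.0, 30.0, 0.5), (2.0, 77.0, 0.5), (0.6, 120.0, 0.5),
        (5.0, 5.0, 1.0), (1.5, 179.0, 0.3),
    ])
    def test_matches_arctangent_oracle(self, r, theta, L):
        # arccos loses a few digits near the poles relative to arctangent
        assert q.geometry_factor(r, theta, L) == pytest.approx(
            geometry_oracle(r, theta, L), rel=1e-10
        )

    @settings(deadline=None, max_examples=200)
    @given(
        r=st.floats(0.3, 15.0),
        theta=st.floats(1.0, 179.0),
        L=st.floats(0.1, 0.5),
    )
    def test_transverse_mirror_symmetry(self, r, theta, L):
        a = q.geometry_factor(r, theta, L)
        b = q.geometry_factor(r, 180.0 - theta, L)
        assert a == pytest.approx(b, rel=1e-10)

    @pytest.mark.parametrize("r", [1.0, 2.0, 5.0])
    def test_pole_branch_continuity(self, r):
        near = q.geometry_factor(r, 1e-3, 0.5)
        pole = q.geometry_factor(r, 0.0, 0.5)
        assert abs(near / pole - 1) < 1e-4

    def test_point_source_limit_uniform_in_theta(self):
        r = 1.0
        L = 1e-4 * r
        for theta in (5.0, 30.0, 90.0, 150.0, 175.0):
            assert r * r * q.geometry_factor(r, theta, L) == pytest.approx(
                1.0, abs=1e-4
            )

    def test_rejects_point_on_source_segment(self):
        with pytest.raises(DomainError):
            q.geometry_factor(0.2, 0.0, 0.5)

    def test_rejects_theta_outside_range(self):
        with pytest.raises(DomainError):
            q.geometry_factor(1.0, 181.0, 0.5)
        with pytest.raises(DomainError):
            q.geometry_factor(1.0, -1.0, 0.5)


class TestRadialDose:
    def test_polynomial_normalized_at_r0(self):
        m = q.make_radial_model("polynomial")
        assert q.radial_dose(1.0, m) == pytest.approx(1.0, abs=1e-12)

    def test_table_node_values_exact(self):
        m = q.RadialDoseModel.from_table([0.5, 1.0, 2.0, 4.0], [1.04, 1.0, 0.98, 0.90])
        for r, g in zip((0.5, 1.0, 2.0, 4.0), (1.04, 1.0, 0.98, 0.90)):
            assert q.radial_dose(r, m) == g

    def test_log_linear_geometric_mean(self):
        # ln g linear in ln r: the geometric-mean radius maps to the
        # geometric mean of the node values, sqrt(0.98*0.90)
        m = q.RadialDoseModel.from_table(
            [1.0, 2.0, 4.0], [1.0, 0.98, 0.90], interpolation="log-linear"
        )
        r_geo = math.sqrt(2.0 * 4.0)
        assert q.radial_dose(r_geo, m) == pytest.approx(
            math.sqrt(0.98 * 0.90), rel=1e-12
        )
        assert q.radial_dose(r_geo, m) == pytest.approx(0.9391486, abs=1e-7)

    def test_out_of_range_reject_and_clamp(self):
        m = q.RadialDoseModel.from_table([0.5, 1.0, 2.0], [1.02, 1.0, 0.97])
        with pytest.raises(DomainError):
            q.radial_dose(3.0, m)
        mc = q.RadialDoseModel.from_table(
            [0.5, 1.0, 2.0], [1.02, 1.0, 0.97], out_of_range="clamp"
        )
        assert q.radial_dose(3.0, mc) == 0.97

    def test_unnormalized_model_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            q.RadialDoseModel.from_polynomial((1.05, 0.01), valid_range=(0.1, 10))

    def test_descending_table_radii_rejected(self):
        with pytest.raises(ValueError):
            q.RadialDoseModel.from_table([2.0, 1.0], [0.98, 1.0])


class TestAnisotropyTable:
    def test_node_identity_over_whole_grid(self, dense_table):
        R, A = np.meshgrid(dense_table.radii, dense_table.angles, indexing="ij")
        vals = q.anisotropy_lookup(R.ravel(), A.ravel(), dense_table)
        assert np.array_equal(vals.reshape(R.shape), dense_table.values)

    def test_bilinear_cell_midpoint(self):
        t = q.AnisotropyTable(
            radii=[1.0, 2.0], angles=[30.0, 60.0],
            values=[[0.4, 0.6], [0.4, 0.6]], theta_zero="tip",
        )
        assert q.anisotropy_lookup(1.5, 45.0, t) == pytest.approx(0.5)

    def test_interpolation_bounded_by_cell_extrema(self):
        rng = np.random.default_rng(42)
        radii = np.sort(rng.uniform(0.5, 10, 8))
        angles = np.sort(rng.uniform(5, 175, 12))
        vals = rng.uniform(0.3, 1.0, (8, 12))
        t = q.AnisotropyTable(radii=radii, angles=angles, values=vals)
        rq = np.linspace(radii[0], radii[-1], 50)
        aq = np.linspace(angles[0], angles[-1], 50)
        for rv in rq:
            got = q.anisotropy_lookup(np.full(50, rv), aq, t)
            i = np.clip(np.searchsorted(radii, rv) - 1, 0, 6)
            for g, av in zip(got, aq):
                j = np.clip(np.searchsorted(angles, av) - 1, 0, 10)
                cell = vals[i:i + 2, j:j + 2]
                assert cell.min() - 1e-12 <= g <= cell.max() + 1e-12

    def test_radial_clamp_outside_range(self, dense_table):
        inner = q.anisotropy_lookup(dense_table.radii[0], 45.0, dense_table)
        assert q.anisotropy_lookup(0.1, 45.0, dense_table) == inner

    def test_transverse_column_must_be_unity(self):
        with pytest.raises(ValueError, match="90"):
            q.AnisotropyTable(
                radii=[1.0, 2.0], angles=[45.0, 90.0],
                values=[[0.9, 0.95], [0.9, 0.95]],
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            q.AnisotropyTable(radii=[1.0], angles=[10.0, 20.0], values=[[0.5]])


class TestPoleExtrapolate:
    def test_tip_side_line_through_two_points(self):
        t = q.AnisotropyTable(
            radii=[1.0, 2.0], angles=[3.0, 6.0, 90.0],
            values=[[0.52, 0.56, 1.0], [0.52, 0.56, 1.0]],
        )
        assert q.pole_extrapolate(t, 1.0, 0) == pytest.approx(0.48)

    def test_cable_side_line_through_two_points(self):
        t = q.AnisotropyTable(
            radii=[1.0, 2.0], angles=[90.0, 174.0, 177.0],
            values=[[1.0, 0.60, 0.58], [1.0, 0.60, 0.58]],
        )
        assert q.pole_extrapolate(t, 1.0, 180) == pytest.approx(0.56)

    def test_positivity_floor(self):
        t = q.AnisotropyTable(
            radii=[1.0, 2.0], angles=[3.0, 30.0, 90.0],
            values=[[0.05, 0.9, 1.0], [0.05, 0.9, 1.0]],
        )
        # the fit would go negative at 0 deg; the floor keeps it positive
        assert q.pole_extrapolate(t, 1.0, 0) == pytest.approx(1e-3)

    def test_needs_two_angles_on_that_side(self):
        t = q.AnisotropyTable(
            radii=[1.0, 2.0], angles=[80.0, 90.0, 100.0, 120.0],
            values=[[0.99, 1.0, 0.99, 0.97]] * 2,
        )
        with pytest.raises(ValueError):
            q.pole_extrapolate(t, 1.0, 0)


class TestDoseRate:
    def test_reference_point_normalization(self, source, radial_model, dense_table):
        d = q.dose_rate(q.PolarPoint(1.0, 90.0), source, radial_model, dense_table)
        assert d == pytest.approx(
            source.air_kerma_strength * source.dose_rate_constant, rel=1e-6
        )

    def test_linear_in_air_kerma_strength(self, radial_model, dense_table):
        s1 = q.default_source(air_kerma_strength=1.0)
        s2 = q.default_source(air_kerma_strength=2.0)
        for r, th in ((0.7, 40.0), (2.0, 120.0), (5.0, 90.0)):
            d1 = q.dose_rate((r, th), s1, radial_model, dense_table)
            d2 = q.dose_rate((r, th), s2, radial_model, dense_table)
            assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_factor_product_oracle(self, source, radial_model, dense_table):
        r, th = 2.3, 37.0
        eng = q.TG43Engine(source, radial_model, dense_table)
        # the synthetic table is cable-at-0, so the engine flips theta
        expected = (
            source.air_kerma_strength
            * source.dose_rate_constant
            * q.geometry_factor(r, th, source.active_length)
            / q.geometry_factor(source.r0, source.theta0, source.active_length)
            * q.radial_dose(r, radial_model)
            * q.anisotropy_lookup(r, 180.0 - th, dense_table)
        )
        assert eng.dose_rate(r, th) == pytest.approx(expected, rel=1e-12)

    def test_orientation_flip_changes_pole_values(self, source, radial_model, dense_table):
        eng = q.TG43Engine(source, radial_model, dense_table)
        # the synthetic table is asymmetric, so tip and cable cones differ
        assert eng.dose_rate(2.0, 7.0) != pytest.approx(
            eng.dose_rate(2.0, 173.0), rel=1e-3
        )


class TestSourceModelValidation:
    def test_r0_must_clear_half_length(self):
        with pytest.raises(ValueError):
            q.SourceModel(active_length=3.0, dose_rate_constant=1.1,
                          air_kerma_strength=1.0, r0=1.0)

    def test_positive_parameters_required(self):
        with pytest.raises(ValueError):
            q.SourceModel(active_length=-0.5, dose_rate_constant=1.1,
                          air_kerma_strength=1.0)
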