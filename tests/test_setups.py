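"""Tests for dwell configurations, plane superposition and summaries."""

import numpy as np
import pytest

import tg43qa as q


@pytest.fixture(scope="module")
def coarse_grid():
    return q.GridSpec(half_width=3.0, spacing=0.1)


class TestMakeSetup:
    def test_one_dwell_at_origin(self):
        s = q.make_setup("one_dwell")
        assert s.n_dwells == 1
        assert np.array_equal(s.positions, [[0.0, 0.0]])

    def test_short_applicator_spacing(self):
        s = q.make_setup("short_applicator")
        assert s.n_dwells == 6
        z = np.sort(s.positions[:, 1])
        assert z[-1] - z[0] == pytest.approx(3.5)
        assert np.allclose(np.diff(z), 0.7)

    def test_long_applicator_default_count(self):
        s = q.make_setup("long_applicator")
        z = np.sort(s.positions[:, 1])
        assert s.n_dwells == 19
        assert z[-1] - z[0] == pytest.approx(9.0)

    def test_fletcher_geometry(self):
        dwells, abs_pts = q.make_setup("fletcher")
        tandem_z = dwells.positions[dwells.positions[:, 0] == 0.0, 1]
        assert tandem_z.max() - tandem_z.min() == pytest.approx(6.0)
        ovoids = dwells.positions[dwells.positions[:, 0] != 0.0]
        assert ovoids.shape[0] == 2
        assert set(abs_pts.points) >= {"point_A_right", "tandem_tip", "rectal",
                                       "bladder"}

    def test_multi_applicator_pitch(self):
        s = q.make_setup("multi_applicator", n_applicators=3, pitch=1.5)
        ys = np.unique(s.positions[:, 0])
        assert np.allclose(ys, [-1.5, 0.0, 1.5])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            q.make_setup("short_applicator", short_span=-1.0)
        with pytest.raises(ValueError):
            q.make_setup("no_such_setup")


class TestDosePlaneSuperposition:
    def test_single_dwell_matches_engine(self, engine_pair, coarse_grid):
        ref_eng, _ = engine_pair
        plane = q.compute_dose_plane(q.make_setup("one_dwell"), coarse_grid, ref_eng)
        # sample an off-axis unmasked point
        iy = np.searchsorted(plane.y_axis, 1.0)
        iz = np.searchsorted(plane.z_axis, 2.0)
        y, z = plane.y_axis[iy], plane.z_axis[iz]
        p = q.cartesian_to_polar((y, z))
        assert plane.values[iz, iy] == pytest.approx(
            float(ref_eng.dose_rate_per_sk(p.r, p.theta)), rel=1e-12
        )

    def test_colocated_dwells_double_dose(self, engine_pair, coarse_grid):
        ref_eng, _ = engine_pair
        one = q.make_setup("one_dwell")
        two = q.DwellSet("pair", [[0, 0], [0, 0]], [[0, 1], [0, 1]], [1.0, 1.0])
        p1 = q.compute_dose_plane(one, coarse_grid, ref_eng)
        p2 = q.compute_dose_plane(two, coarse_grid, ref_eng)
        ok = np.isfinite(p1.values)
        assert np.allclose(p2.values[ok], 2 * p1.values[ok], rtol=1e-12)

    def test_additivity_over_dwells(self, engine_pair, coarse_grid):
        ref_eng, _ = engine_pair
        setup = q.make_setup("short_applicator")
        total = q.compute_dose_plane(setup, coarse_grid, ref_eng)
        acc = np.zeros_like(total.values)
        for pos in setup.positions:
            single = q.DwellSet("s", [pos], [[0, 1]], [1.0],
                                applicators=setup.applicators)
            acc += np.nan_to_num(
                q.compute_dose_plane(single, coarse_grid, ref_eng).values
            )
        ok = np.isfinite(total.values)
        assert np.allclose(acc[ok], total.values[ok], rtol=1e-12, atol=1e-12)

    def test_weight_linearity(self, engine_pair, coarse_grid):
        ref_eng, _ = engine_pair
        base = q.DwellSet("w1", [[0, 0]], [[0, 1]], [1.0])
        triple = q.DwellSet("w3", [[0, 0]], [[0, 1]], [3.0])
        p1 = q.compute_dose_plane(base, coarse_grid, ref_eng)
        p3 = q.compute_dose_plane(triple, coarse_grid, ref_eng)
        ok = np.isfinite(p1.values)
        assert np.allclose(p3.values[ok], 3 * p1.values[ok], rtol=1e-12)

    def test_mirror_symmetry_tracks_table_symmetry(self, source, radial_model,
                                                   coarse_grid):
        sym_spec = q.SyntheticAnisotropySpec(amp_cable=0.5, width_cable=8.0,
                                             amp_tip=0.5, width_tip=8.0)
        sym_table = q.make_reference_anisotropy(sym_spec)
        eng_sym = q.TG43Engine(source, radial_model, sym_table)
        plane = q.compute_dose_plane(q.make_setup("one_dwell"), coarse_grid, eng_sym)
        flipped = plane.values[::-1, :]
        ok = np.isfinite(plane.values) & np.isfinite(flipped)
        assert np.allclose(plane.values[ok], flipped[ok], rtol=1e-9)

        asym = q.make_reference_anisotropy(q.SyntheticAnisotropySpec())
        eng_asym = q.TG43Engine(source, radial_model, asym)
        plane2 = q.compute_dose_plane(q.make_setup("one_dwell"), coarse_grid, eng_asym)
        flipped2 = plane2.values[::-1, :]
        ok2 = np.isfinite(plane2.values) & np.isfinite(flipped2)
        assert not np.allclose(plane2.values[ok2], flipped2[ok2], rtol=1e-3)


class TestDiffAndSummary:
    def test_identical_planes_zero_diff(self, engine_pair, coarse_grid):
        ref_eng, _ = engine_pair
        p = q.compute_dose_plane(q.make_setup("one_dwell"), coarse_grid, ref_eng)
        d = q.percent_diff_plane(p, p)
        assert np.nanmax(np.abs(d.values)) == 0.0

    def test_uniform_scaling_gives_constant_diff(self, engine_pair, coarse_grid):
        ref_eng, _ = engine_pair
        p = q.compute_dose_plane(q.make_setup("one_dwell"), coarse_grid, ref_eng)
        scaled = q.DosePlane(y_axis=p.y_axis, z_axis=p.z_axis,
                             values=0.9 * p.values, spacing=p.spacing)
        d = q.percent_diff_plane(scaled, p)
        fv = d.finite_values
        assert np.allclose(fv, -10.0, atol=1e-9)

    def test_grid_mismatch_rejected(self, engine_pair, coarse_grid):
        ref_eng, _ = engine_pair
        p = q.compute_dose_plane(q.make_setup("one_dwell"), coarse_grid, ref_eng)
        other = q.compute_dose_plane(
            q.make_setup("one_dwell"), q.GridSpec(half_width=2.0, spacing=0.1),
            ref_eng,
        )
        with pytest.raises(ValueError):
            q.percent_diff_plane(p, other)

    def test_summary_constant_map(self):
        d = q.DiffMap(axis1=[0.0, 1.0], axis2=[0.0, 1.0],
                      values=np.full((2, 2), 3.5), kind="cartesian")
        s = q.setup_summary(d)
        assert s["mean"] == s["median"] == 3.5
        assert s["sd"] == 0.0 and (s["min"], s["max"]) == (3.5, 3.5)

    def test_summary_small_example(self):
        d = q.DiffMap(axis1=[0.0, 1.0], axis2=[0.0, 1.0],
                      values=np.array([[1.0, 2.0], [3.0, 4.0]]), kind="cartesian")
        s = q.setup_summary(d)
        assert s["median"] == 2.5 and s["mean"] == 2.5

    def test_summary_against_two_pass_oracle(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(0, 3, (100, 100))
        d = q.DiffMap(axis1=np.arange(100.0), axis2=np.arange(100.0),
                      values=vals, kind="cartesian")
        s = q.setup_summary(d)
        n = vals.size
        mean = vals.sum() / n
        var = ((vals - mean) ** 2).sum() / (n - 1)
        assert s["mean"] == pytest.approx(mean, abs=1e-10)
        assert s["sd"] == pytest.approx(np.sqrt(var), abs=1e-10)

    def test_empty_map_rejected(self):
        d = q.DiffMap(axis1=[0.0], axis2=[0.0],
                      values=np.array([[np.nan]]), kind="cartesian")
        with pytest.raises(ValueError):
            q.setup_summary(d)


class TestOdinLocalisationOnPlanes:
    def test_one_dwell_extreme_within_pole_cone(self, engine_pair, coarse_grid):
        ref_eng, ven_eng = engine_pair
        one = q.make_setup("one_dwell")
        d = q.percent_diff_plane(
            q.compute_dose_plane(one, coarse_grid, ven_eng),
            q.compute_dose_plane(one, coarse_grid, ref_eng),
        )
        v = d.values
        iz, iy = np.unravel_index(np.nanargmin(v), v.shape)
        p = q.cartesian_to_polar((d.axis2[iy], d.axis1[iz]))
        assert min(p.theta, 180.0 - p.theta) <= 15.0

    def test_multi_applicator_beats_one_dwell(self, engine_pair, coarse_grid):
        ref_eng, ven_eng = engine_pair
        def max_abs(kind):
            made = q.make_setup(kind)
            dwells = made[0] if isinstance(made, tuple) else made
            d = q.percent_diff_plane(
                q.compute_dose_plane(dwells, coarse_grid, ven_eng),
                q.compute_dose_plane(dwells, coarse_grid, ref_eng),
            )
            s = q.setup_summary(d)
            return max(abs(s["min"]), abs(s["max"]))
        assert max_abs("multi_applicator") < max_abs("one_dwell")


class TestAbsPoints:
    def test_identical_planes_zero_everywhere(self, engine_pair):
        ref_eng, _ = engine_pair
        dwells, abs_pts = q.make_setup("fletcher")
        grid = q.GridSpec(half_width=6.0, spacing=0.1, center=dwells.centroid)
        p = q.compute_dose_plane(dwells, grid, ref_eng)
        d = q.percent_diff_plane(p, p)
        vals = q.evaluate_abs_points(abs_pts, d)
        assert all(v == 0.0 for v in vals.values())

    def test_grid_node_exact(self, engine_pair):
        ref_eng, ven_eng = engine_pair
        grid = q.GridSpec(half_width=3.0, spacing=0.1)
        one = q.make_setup("one_dwell")
        d = q.percent_diff_plane(
            q.compute_dose_plane(one, grid, ven_eng),
            q.compute_dose_plane(one, grid, ref_eng),
        )
        iy, iz = 40, 50
        pts = q.AbsPointSet(points={"node": (d.axis2[iy], d.axis1[iz])})
        got = q.evaluate_abs_points(pts, d)["node"]
        assert got == d.values[iz, iy]

    def test_point_outside_plane_rejected(self, engine_pair):
        ref_eng, _ = engine_pair
        grid = q.GridSpec(half_width=2.0, spacing=0.2)
        one = q.make_setup("one_dwell")
        p = q.compute_dose_plane(one, grid, ref_eng)
        d = q.percent_diff_plane(p, p)
        with pytest.raises(ValueError):
            q.evaluate_abs_points(q.AbsPointSet(points={"far": (5.0, 0.0)}), d)

    def test_fletcher_abs_points_milder_than_plane_extreme(self, engine_pair):
        """Reporting-point differences understate the worst pole-cone
        discrepancy — the 2D map reveals what point dosimetry hides."""
        ref_eng, ven_eng = engine_pair
        dwells, abs_pts = q.make_setup("fletcher")
        grid = q.GridSpec(half_width=6.0, spacing=0.1, center=dwells.centroid)
        d = q.percent_diff_plane(
            q.compute_dose_plane(dwells, grid, ven_eng),
            q.compute_dose_plane(dwells, grid, ref_eng),
        )
        s = q.setup_summary(d)
        plane_worst = max(abs(s["min"]), abs(s["max"]))
        vals = q.evaluate_abs_points(abs_pts, d)
        assert all(abs(v) < plane_worst for v in vals.values())
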