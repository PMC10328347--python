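"""Anisotropic Eikonal activation on labelled grids."""

import numpy as np
import pytest

from cardiogsa import eikonal_activation as ek


def _uniform_grid(ny, nx, h=0.5, fibre_axis=1):
    labels = np.full((ny, nx), ek.VENTRICULAR_MYO)
    fibres = np.zeros((ny, nx, 2))
    fibres[..., fibre_axis] = 1.0
    return ek.LabeledGrid(h=h, labels=labels, fibres=fibres)


class TestVelocityField:
    def test_cross_fibre_speed(self):
        grid = _uniform_grid(5, 5)
        field = ek.build_velocity_field(grid, 0.6, 0.4)
        assert field.ct.max() == pytest.approx(0.24)
        assert field.cf.max() == pytest.approx(0.6)

    def test_isotropic_limit(self):
        grid = _uniform_grid(5, 5)
        field = ek.build_velocity_field(grid, 0.6, 1.0)
        np.testing.assert_allclose(field.cf, field.ct)

    def test_fec_scaling_only_inside_layer(self):
        grid, _ = ek.two_slab_grid()
        field = ek.build_velocity_field(
            grid, {"atrial": 0.7, "ventricular": 0.6},
            {"atrial": 0.4, "ventricular": 0.4}, {"FEC": 2.0})
        assert field.cf[grid.labels == ek.FEC].max() == pytest.approx(1.2)
        assert field.cf[grid.labels == ek.VENTRICULAR_MYO].max() == \
            pytest.approx(0.6)

    @pytest.mark.parametrize("cv,kft,scal", [
        (-0.1, 0.4, {}), (0.6, 1.5, {}), (0.6, 0.4, {"FEC": 0.5}),
    ])
    def test_invalid_parameters_rejected(self, cv, kft, scal):
        grid, _ = ek.two_slab_grid()
        with pytest.raises(ValueError):
            ek.build_velocity_field(grid, cv, kft, scal)


class TestSolver:
    def test_homogeneous_point_source(self):
        """Isotropic CV 0.6 mm/ms at h = 0.5 mm: a node 60 mm along the
        grid axis activates at 100 ms; off-axis within 2%."""
        grid = _uniform_grid(41, 125)
        field = ek.build_velocity_field(grid, 0.6, 1.0)
        amap = ek.solve_eikonal(grid, field, [((0, 0), 0.0)])
        assert amap.times[0, 120] == pytest.approx(100.0, rel=1e-6)
        exact = np.hypot(20.0, 40.0) / 0.6
        assert amap.times[40, 80] == pytest.approx(exact, rel=0.02)

    def test_anisotropic_cross_fibre_ray(self):
        """Fibres along x, k_ft = 0.4: 24 mm across the fibre at
        CV_f = 0.6 arrives at 24 / 0.24 = 100 ms."""
        grid = _uniform_grid(49, 21, h=0.5)
        field = ek.build_velocity_field(grid, 0.6, 0.4)
        amap = ek.solve_eikonal(grid, field, [((0, 10), 0.0)])
        assert amap.times[48, 10] == pytest.approx(100.0, rel=0.02)

    def test_two_source_superposition(self):
        grid = _uniform_grid(21, 21, h=1.0)
        field = ek.build_velocity_field(grid, 0.5, 0.4)
        m1 = ek.solve_eikonal(grid, field, [((0, 0), 0.0)])
        m2 = ek.solve_eikonal(grid, field, [((20, 20), 50.0)])
        m12 = ek.solve_eikonal(grid, field,
                               [((0, 0), 0.0), ((20, 20), 50.0)])
        ref = np.minimum(m1.times, m2.times)
        # first arrival with both sources can only be earlier; at the shock
        # line where the two fronts meet the simplex interpolation
        # undershoots by O(h), hence the one-sided tolerance
        assert (m12.times <= ref + 1e-9).all()
        np.testing.assert_allclose(m12.times, ref, rtol=5e-3)

    def test_causality(self):
        grid = _uniform_grid(15, 15)
        field = ek.build_velocity_field(grid, 0.6, 0.5)
        amap = ek.solve_eikonal(grid, field, [((7, 7), 5.0)])
        assert np.isfinite(amap.times).all()
        assert amap.times.min() == 5.0

    def test_first_order_convergence(self):
        """Error against the analytic homogeneous solution drops when h
        is halved."""
        def err(h):
            ny, nx = int(20 / h) + 1, int(40 / h) + 1
            grid = _uniform_grid(ny, nx, h=h)
            field = ek.build_velocity_field(grid, 0.5, 1.0)
            amap = ek.solve_eikonal(grid, field, [((0, 0), 0.0)])
            return abs(amap.times[-1, -1] - np.hypot(20.0, 40.0) / 0.5)

        assert err(0.5) < err(1.0)

    def test_discrete_solution_below_graph_dijkstra(self):
        """Two-point simplex updates can only improve on pure edge-graph
        shortest paths; both stay within a few percent of the metric."""
        from scipy.sparse import lil_matrix
        from scipy.sparse.csgraph import dijkstra as graph_dijkstra

        ny = nx = 25
        grid = _uniform_grid(ny, nx, h=1.0)
        field = ek.build_velocity_field(grid, 0.5, 1.0)
        amap = ek.solve_eikonal(grid, field, [((0, 0), 0.0)])

        n = ny * nx
        W = lil_matrix((n, n))
        for iy in range(ny):
            for ix in range(nx):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if dy == dx == 0:
                            continue
                        jy, jx = iy + dy, ix + dx
                        if 0 <= jy < ny and 0 <= jx < nx:
                            W[iy * nx + ix, jy * nx + jx] = \
                                np.hypot(dy, dx) / 0.5
        ref = graph_dijkstra(W.tocsr(), indices=0).reshape(ny, nx)
        assert (amap.times <= ref + 1e-9).all()
        # the graph metric overestimates by up to sec(22.5 deg) - 1 ~ 8%
        assert np.abs(amap.times - ref).max() / ref.max() < 0.10

    def test_source_outside_conducting_region_rejected(self):
        grid, _ = ek.two_slab_grid()
        iy = int(np.argwhere(grid.labels[:, 0] == ek.AV_INSULATION)[0][0])
        field = ek.build_velocity_field(grid, 0.6, 0.4)
        with pytest.raises(ValueError, match="conducting"):
            ek.solve_eikonal(grid, field, [((iy, 0), 0.0)])


class TestDualSite:
    @pytest.fixture(scope="class")
    def setup(self):
        grid, sites = ek.two_slab_grid()
        field = ek.build_velocity_field(
            grid, {"atrial": 0.7, "ventricular": 0.6},
            {"atrial": 0.4, "ventricular": 0.4}, {"FEC": 3.0, "BB": 3.0})
        return grid, sites, field

    def test_earliest_ventricular_activation_is_av_delay(self, setup):
        grid, sites, field = setup
        amap = ek.dual_site_initiation(grid, field, sites["atrial"],
                                       sites["ventricular"], 150.0)
        vmask = np.isin(grid.labels, list(ek.VENTRICULAR_GROUP))
        assert amap.times[vmask].min() == pytest.approx(150.0)

    def test_av_delay_bounds_enforced(self, setup):
        grid, sites, field = setup
        with pytest.raises(ValueError, match="bounds"):
            ek.dual_site_initiation(grid, field, sites["atrial"],
                                    sites["ventricular"], 50.0)

    def test_atrial_map_unchanged_by_ventricular_source(self, setup):
        grid, sites, field = setup
        solo = ek.solve_eikonal(grid, field, [(sites["atrial"], 0.0)])
        dual = ek.dual_site_initiation(grid, field, sites["atrial"],
                                       sites["ventricular"], 150.0)
        amask = np.isin(grid.labels, list(ek.ATRIAL_GROUP))
        np.testing.assert_allclose(dual.times[amask], solo.times[amask],
                                   atol=1e-9)

    def test_insulation_blocks_atrial_wavefront(self, setup):
        grid, sites, field = setup
        solo = ek.solve_eikonal(grid, field, [(sites["atrial"], 0.0)])
        vmask = np.isin(grid.labels, list(ek.VENTRICULAR_GROUP))
        assert not np.isfinite(solo.times[vmask]).any()


class TestTotalActivationTime:
    def test_uniform_strip(self):
        grid = _uniform_grid(1, 41, h=1.0)
        field = ek.build_velocity_field(grid, 0.5, 1.0)
        amap = ek.solve_eikonal(grid, field, [((0, 0), 0.0)])
        tat = ek.total_activation_time(amap, [ek.VENTRICULAR_MYO])
        assert tat == pytest.approx(40.0 / 0.5, rel=0.01)

    def test_doubling_cv_halves_tat(self):
        grid = _uniform_grid(11, 41, h=1.0)
        tats = []
        for cv in (0.5, 1.0):
            field = ek.build_velocity_field(grid, cv, 0.4)
            amap = ek.solve_eikonal(grid, field, [((0, 0), 0.0)])
            tats.append(ek.total_activation_time(amap, [ek.VENTRICULAR_MYO]))
        assert tats[0] == pytest.approx(2.0 * tats[1], rel=1e-6)

    def test_unreachable_nodes_rejected_with_count(self):
        grid, sites = ek.two_slab_grid()
        field = ek.build_velocity_field(
            grid, {"atrial": 0.7, "ventricular": 0.6},
            {"atrial": 0.4, "ventricular": 0.4})
        amap = ek.solve_eikonal(grid, field, [(sites["atrial"], 0.0)])
        with pytest.raises(ValueError, match="unreachable"):
            ek.total_activation_time(amap, ek.VENTRICULAR_GROUP)


def test_three_dimensional_slab():
    grid, sites = ek.two_slab_grid(nx=21, ny_vent=8, ny_atria=6, nz=3)
    assert grid.dim == 3
    field = ek.build_velocity_field(
        grid, {"atrial": 0.7, "ventricular": 0.6},
        {"atrial": 0.4, "ventricular": 0.4}, {"FEC": 3.0, "BB": 3.0})
    amap = ek.dual_site_initiation(grid, field, sites["atrial"],
                                   sites["ventricular"], 120.0)
    tat_v = ek.total_activation_time(amap, ek.VENTRICULAR_GROUP)
    tat_a = ek.total_activation_time(amap, ek.ATRIAL_GROUP)
    assert 0 < tat_v < 500 and 0 < tat_a < 500
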