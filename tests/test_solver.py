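import numpy as np
import pytest

from aratile.kernels import build_interaction_matrix, evaluate_kernel
from aratile.points import PointSet
from aratile.solver import (
    CFLError,
    ConfigurationError,
    Grid,
    Simulation,
    SpeciesState,
    disk_initial,
    initial_from_points,
    nonlocal_term,
)

from conftest import NARROW_TERRACE, UNIT_KERNEL


def brute_force_nonlocal(u, params, grid):
    """Independent evaluation of the discrete nonlocal drift.

    Direct sum over every cell-centre offset inside the sensing disk:
    K(x) = sum_y u(x + y) omega(|y|) y/|y| dx^2, with the half-open band
    convention applied at exact breakpoint radii.
    """
    N, dx = grid.N, grid.dx
    K = np.zeros((2, N, N))
    for oy in range(N):
        sy = oy if oy <= N // 2 else oy - N
        for ox in range(N):
            sx = ox if ox <= N // 2 else ox - N
            yy, xx = sy * dx, sx * dx
            r = np.hypot(xx, yy)
            if r == 0 or r >= 1:
                continue
            w = evaluate_kernel(r, params) * dx * dx
            if w == 0:
                continue
            shifted = np.roll(np.roll(u, -sy, axis=0), -sx, axis=1)
            K[0] += w * (xx / r) * shifted
            K[1] += w * (yy / r) * shifted
    return K


def polar_quadrature_nonlocal(u, params, grid, n_r=400, n_theta=256):
    """Polar-node quadrature with periodic bilinear interpolation.

    Midpoint rule in radius and angle; a genuinely different discretisation
    of the same integral, so it agrees with the stencil only up to
    discretisation error.
    """
    N, dx, L = grid.N, grid.dx, grid.L
    r = (np.arange(n_r) + 0.5) / n_r
    th = (np.arange(n_theta) + 0.5) * 2 * np.pi / n_theta
    w_r = evaluate_kernel(r, params) * r / n_r
    K = np.zeros((2, N, N))

    def sample(dx_off, dy_off):
        # periodic bilinear interpolation of u at (x + off) for all cells
        gx = dx_off / dx
        gy = dy_off / dx
        i0x, fx = int(np.floor(gx)), gx - np.floor(gx)
        i0y, fy = int(np.floor(gy)), gy - np.floor(gy)
        u00 = np.roll(u, (-i0y, -i0x), axis=(0, 1))
        u01 = np.roll(u, (-i0y, -i0x - 1), axis=(0, 1))
        u10 = np.roll(u, (-i0y - 1, -i0x), axis=(0, 1))
        u11 = np.roll(u, (-i0y - 1, -i0x - 1), axis=(0, 1))
        return ((1 - fy) * ((1 - fx) * u00 + fx * u01)
                + fy * ((1 - fx) * u10 + fx * u11))

    dth = 2 * np.pi / n_theta
    for j, t in enumerate(th):
        ex, ey = np.cos(t), np.sin(t)
        for i, ri in enumerate(r):
            if w_r[i] == 0:
                continue
            s = sample(ri * ex, ri * ey) * w_r[i] * dth
            K[0] += s * ex
            K[1] += s * ey
    return K


class TestGrid:
    def test_odd_or_nonpositive_N_rejected(self):
        with pytest.raises(ConfigurationError):
            Grid(127)
        with pytest.raises(ConfigurationError):
            Grid(0)

    def test_domain_must_contain_sensing_radius(self):
        with pytest.raises(ConfigurationError, match="sensing radius"):
            Grid(64, L=0.8)

    def test_cell_geometry(self):
        g = Grid(128)
        assert g.dx == pytest.approx(5.6 / 128)
        assert g.axis()[0] == pytest.approx(-2.8 + g.dx / 2)


class TestNonlocalTerm:
    def test_constant_field_zero_drift(self):
        g = Grid(32)
        K = nonlocal_term(np.full((32, 32), 0.7), UNIT_KERNEL, g)
        assert np.abs(K).max() < 1e-12

    def test_point_mass_attraction_direction(self):
        g = Grid(128)
        ax = g.axis()
        u = np.zeros((128, 128))
        iy = np.argmin(np.abs(ax))
        ix = np.argmin(np.abs(ax - 0.6))
        u[iy, ix] = 1.0
        K = nonlocal_term(u, NARROW_TERRACE, g)
        i0 = np.argmin(np.abs(ax))
        # at the origin the mass sits 0.6 away: attraction band, pull in +x
        assert K[0, i0, i0] == pytest.approx(
            NARROW_TERRACE.Fa * g.cell_area, rel=1e-12
        )
        assert abs(K[1, i0, i0]) < 1e-12

    @pytest.mark.parametrize("N", [32, 48])
    def test_fft_matches_brute_force(self, N, rng):
        g = Grid(N)
        u = rng.random((N, N))
        K_fft = nonlocal_term(u, UNIT_KERNEL, g, method="fft")
        K_ref = brute_force_nonlocal(u, UNIT_KERNEL, g)
        assert np.abs(K_fft - K_ref).max() < 1e-12

    def test_direct_method_matches_fft(self, rng):
        g = Grid(32)
        u = rng.random((32, 32))
        K_fft = nonlocal_term(u, UNIT_KERNEL, g, method="fft")
        K_dir = nonlocal_term(u, UNIT_KERNEL, g, method="direct")
        assert np.abs(K_fft - K_dir).max() < 1e-12

    def test_polar_quadrature_cross_check(self):
        # smooth density: the stencil agrees with an independent polar-node
        # quadrature to discretisation error (O(dx) at the band jumps), and
        # the discrepancy shrinks as the grid is refined
        errs = {}
        for N in (48, 96):
            g = Grid(N)
            ax = g.axis()
            X, Y = np.meshgrid(ax, ax, indexing="xy")
            u = np.exp(-((X - 0.3) ** 2 + Y**2) / 0.5)
            K_st = nonlocal_term(u, UNIT_KERNEL, g)
            K_pol = polar_quadrature_nonlocal(u, UNIT_KERNEL, g,
                                              n_r=200, n_theta=128)
            errs[N] = np.abs(K_st - K_pol).max() / np.abs(K_pol).max()
        assert errs[96] < 0.12
        assert errs[96] < errs[48]


class TestInitialConditions:
    def test_disk_mass_matches_area(self):
        g = Grid(128)
        f = disk_initial(g)
        mass = f.sum() * g.cell_area
        assert mass == pytest.approx(0.1 * np.pi * 0.04, abs=g.cell_area)

    def test_zero_radius_gives_zero_field(self):
        g = Grid(64)
        assert not disk_initial(g, radius=0.0).any()

    def test_level_scales_linearly(self):
        g = Grid(64)
        np.testing.assert_array_equal(
            disk_initial(g, level=0.2), 2.0 * disk_initial(g, level=0.1)
        )

    def test_bands_from_single_center(self):
        g = Grid(128)
        fields = initial_from_points(PointSet([[0.0, 0.0]]), g)
        ax = g.axis()
        X, Y = np.meshgrid(ax, ax, indexing="xy")
        d = np.hypot(X, Y)
        np.testing.assert_array_equal(fields[0], np.where(d < 0.04, 0.2, 0.0))
        np.testing.assert_array_equal(
            fields[1], np.where((d >= 0.04) & (d < 0.12), 0.1, 0.0)
        )
        np.testing.assert_array_equal(fields[2], np.where(d >= 0.12, 0.04, 0.0))

    def test_bands_disjoint(self):
        g = Grid(96)
        pts = PointSet([[0.3, -0.2], [-0.9, 1.4], [1.8, 0.7]])
        f = initial_from_points(pts, g)
        assert not (f[0] * f[1]).any()
        assert not (f[0] * f[2]).any()

    def test_background_species_fills_far_field(self):
        g = Grid(96)
        f = initial_from_points(PointSet([[0.0, 0.0], [0.61, 0.0]]), g)
        ax = g.axis()
        X, Y = np.meshgrid(ax, ax, indexing="xy")
        d = np.minimum(np.hypot(X, Y), np.hypot(X - 0.61, Y))
        np.testing.assert_array_equal(f[2] == 0.0, d < 0.12)

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            initial_from_points(np.empty((0, 2)), Grid(64))


class TestStepping:
    def test_zero_state_is_fixed_point(self):
        g = Grid(64)
        sim = Simulation(g, UNIT_KERNEL, check_resolution=False)
        st = sim.step(SpeciesState(np.zeros((64, 64))), dt=1e-3)
        assert not st.fields.any()

    def test_uniform_field_is_fixed_point(self):
        g = Grid(64)
        sim = Simulation(g, UNIT_KERNEL, check_resolution=False)
        st0 = SpeciesState(np.full((64, 64), 0.4))
        st1 = sim.step(st0)
        np.testing.assert_allclose(st1.fields, 0.4, atol=1e-13)

    def test_mass_conserved_and_nonnegative(self):
        g = Grid(128)
        sim = Simulation(g, NARROW_TERRACE)
        st = SpeciesState(disk_initial(g))
        m0 = st.mass(g)
        for _ in range(50):
            st = sim.step(st)
        m1 = st.mass(g)
        assert abs(m1[0] - m0[0]) < 1e-12 * m0[0]
        assert st.fields.min() >= 0.0

    def test_three_species_mass_conserved(self):
        g = Grid(128)
        matrix = build_interaction_matrix({"Fa_11": 300.0, "R2_11": 0.64})
        sim = Simulation(g, matrix)
        pts = PointSet([[0.0, 0.0], [0.61, 0.0], [0.3, 0.55]])
        st = SpeciesState(initial_from_points(pts, g))
        m0 = st.mass(g)
        for _ in range(25):
            st = sim.step(st)
        np.testing.assert_allclose(st.mass(g), m0, rtol=1e-12)
        assert st.fields.min() >= 0.0

    def test_cfl_violation_reports_admissible_dt(self):
        g = Grid(128)
        sim = Simulation(g, NARROW_TERRACE)
        st = SpeciesState(disk_initial(g))
        adm = sim.admissible_dt(st)
        with pytest.raises(CFLError) as err:
            sim.step(st, dt=10 * adm)
        assert err.value.admissible == pytest.approx(adm)

    def test_underresolved_adhesion_band_rejected(self):
        with pytest.raises(ConfigurationError, match="R0/3"):
            Simulation(Grid(32), NARROW_TERRACE)

    def test_quarter_turn_symmetry_preserved(self):
        # D4-symmetric data stays D4-symmetric under the evolution
        g = Grid(64)
        sim = Simulation(g, UNIT_KERNEL, check_resolution=False)
        st = SpeciesState(disk_initial(g, level=0.3, radius=0.8))
        np.testing.assert_allclose(st.fields[0], np.rot90(st.fields[0]),
                                   atol=0)
        out = sim.advance_to(st, 0.2)
        np.testing.assert_allclose(out.fields[0], np.rot90(out.fields[0]),
                                   atol=1e-12)


class TestRunToSteady:
    def test_uniform_converges_immediately(self):
        g = Grid(64)
        sim = Simulation(g, UNIT_KERNEL, check_resolution=False)
        res = sim.run_to_steady(SpeciesState(np.full((64, 64), 0.3)), tol=1e-5)
        assert res.converged
        assert res.state.t == pytest.approx(1.0)
        assert len(res.residuals) == 1

    def test_cap_flags_nonconvergence(self):
        g = Grid(128)
        sim = Simulation(g, NARROW_TERRACE)
        res = sim.run_to_steady(SpeciesState(disk_initial(g)), tol=1e-12,
                                t_max=2.0)
        assert not res.converged
        assert res.state.t == pytest.approx(2.0)
        # residual log is recorded at unit-time checkpoints
        assert [t for t, _ in res.residuals] == pytest.approx([1.0, 2.0])

    def test_bad_tolerance_rejected(self):
        g = Grid(64)
        sim = Simulation(g, UNIT_KERNEL, check_resolution=False)
        with pytest.raises(ValueError):
            sim.run_to_steady(SpeciesState(np.zeros((64, 64))), tol=0.0)
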