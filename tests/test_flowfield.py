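"""Flow solver against Couette/clean-interface limits and refinement studies."""

import numpy as np
import pytest

from rheoref.flowfield import (
    FLUID_SUB,
    INTERFACE,
    PROBE,
    WALL,
    build_mesh,
    compute_drags,
    solve_field,
    wetted_surface_torque,
)
from rheoref.geometry import AIR, DWRGeometry, WATER, g1_coefficient


@pytest.fixture(scope="module")
def mesh16(geom):
    return build_mesh(geom, 16)


class TestBuildMesh:
    def test_nodes_across_wall_gaps(self, geom):
        m = build_mesh(geom, 8)
        assert m.i_R4 >= 8  # >= 8 intervals across [R_i, R4]
        assert np.isclose(m.r[m.i_R4], geom.R4)
        assert np.isclose(m.r[m.i_R5], geom.R5)
        assert np.isclose(m.r[0], geom.R_i) and np.isclose(m.r[-1], geom.R_o)

    def test_doubling_resolution_halves_spacing(self, geom):
        d1 = build_mesh(geom, 8).dz
        d2 = build_mesh(geom, 16).dz
        assert d1 == pytest.approx(2 * d2, rel=1e-12)

    def test_too_coarse_rejected(self):
        g = DWRGeometry(R_i=22.9e-3)  # inner gap 0.1 mm << ring gap
        with pytest.raises(ValueError):
            build_mesh(g, 8)
        with pytest.raises(ValueError):
            build_mesh(DWRGeometry(), 4)

    def test_probe_mask_is_half_diamond(self, geom):
        m = build_mesh(geom, 16)
        # diamond contact row spans [R4, R5]; vertex n2/2 rows down
        row0 = m.mask[m.j_if, m.i_R4 : m.i_R5 + 1]
        assert np.all(row0 == PROBE)
        assert m.mask[m.j_if + m.n2 // 2, (m.i_R4 + m.i_R5) // 2] == PROBE
        assert m.mask[m.j_if + m.n2 // 2 + 1, (m.i_R4 + m.i_R5) // 2] == FLUID_SUB
        # probe node count converges to the rasterised half diamond area
        n_probe = np.sum(m.mask == PROBE)
        expect = (m.n2 + 1) + sum(m.n2 + 1 - 2 * k for k in range(1, m.n2 // 2 + 1))
        assert n_probe == expect

    def test_contact_lines_on_interface_row(self, geom):
        m = build_mesh(geom, 8)
        assert m.mask[m.j_if, m.i_R4] == PROBE
        assert m.mask[m.j_if, m.i_R4 - 1] == INTERFACE
        assert m.mask[m.j_if, m.i_R5 + 1] == INTERFACE
        assert m.mask[m.j_if, 0] == WALL


class TestSolveField:
    def test_couette_limit_interface_profile(self, geom, mesh16):
        """Bo -> inf, steady: the inner-gap interface velocity is the
        annular-Couette profile C1 r + C2/r (closed-form oracle)."""
        sol = solve_field(mesh16, 1e6, 0.0, (WATER, None))
        r = mesh16.r[: mesh16.i_R4 + 1]
        R_i, R4 = geom.R_i, geom.R4
        C1 = R4**2 / (R4**2 - R_i**2)
        C2 = -(R_i**2) * R4**2 / (R4**2 - R_i**2)
        u_exact = C1 * r + C2 / r
        u_num = sol.u[mesh16.j_if, : mesh16.i_R4 + 1].real
        err = np.max(np.abs(u_num - u_exact)) / np.max(np.abs(u_exact))
        assert err < 5e-3

    def test_stationary_probe_zero_field(self, geom, mesh16):
        """With zero boundary data everywhere the solution vanishes."""
        sol = solve_field(mesh16, 10.0, np.pi, (WATER, None))
        # linearity: subtracting the probe-driven solution from itself
        assert np.allclose(sol.u[mesh16.mask == WALL], 0.0)
        u_probe = sol.u[mesh16.mask == PROBE]
        r_probe = np.broadcast_to(mesh16.r, mesh16.shape)[mesh16.mask == PROBE]
        assert np.allclose(u_probe, r_probe)

    def test_clean_interface_free_surface_condition(self, geom, mesh16):
        """Bo = 0: the free interface carries no stress, du/dz -> 0 there
        (exactly, in the discrete stencil, for the plain solve)."""
        sol = solve_field(
            mesh16, 0.0, 0.0, (WATER, None), corner_correction=False
        )
        j = mesh16.j_if
        i = mesh16.i_R4 // 2
        dudz = (
            3 * sol.u[j, i] - 4 * sol.u[j + 1, i] + sol.u[j + 2, i]
        ) / (2 * mesh16.dz)
        shear_scale = abs(sol.u[j, i]) / (geom.R4 - geom.R_i)
        assert abs(dudz) < 1e-6 * shear_scale

    def test_clean_interface_deep_channel_self_convergence(self, geom):
        """Bo = 0 steady drag agrees with a refined-mesh oracle."""
        k_coarse = compute_drags(
            solve_field(build_mesh(geom, 12), 0.0, 0.0), build_mesh(geom, 12)
        )[1]
        k_fine = compute_drags(
            solve_field(build_mesh(geom, 48), 0.0, 0.0), build_mesh(geom, 48)
        )[1]
        assert abs(k_coarse - k_fine) / abs(k_fine) < 5e-3
        assert k_fine.real > 0.0

    def test_negative_omega_rejected(self, mesh16):
        with pytest.raises(ValueError):
            solve_field(mesh16, 1.0, -1.0)


class TestComputeDrags:
    def test_zero_interfacial_viscosity_zero_interfacial_drag(self, geom, mesh16):
        sol = solve_field(mesh16, 0.0, 0.0, (WATER, None))
        K_i, K_b = compute_drags(sol, mesh16, geom, (WATER, None))
        assert K_i == 0.0
        assert K_b.real > 0.0  # bulk drag is dissipative

    def test_high_bo_elastic_limit_matches_g1(self, geom):
        """iw K_i / G' -> g1 in the elastic-plate limit (geometry module
        cross-oracle), to < 1%."""
        for res in (8, 16):
            m = build_mesh(geom, res)
            sol = solve_field(m, 1e6, 0.0, (WATER, None))
            K_i, _ = compute_drags(sol, m, geom, (WATER, None))
            # steady solve: K_i = eta_s * J; iw K_i/G' = J for G* = iw eta_s
            g1_flow = (K_i / sol.eta_s).real * 1.0
            assert g1_flow == pytest.approx(g1_coefficient(geom), rel=1e-2)

    @pytest.mark.parametrize(
        "geo",
        [
            DWRGeometry(),
            DWRGeometry(R_i=18e-3, R4=22e-3, R5=23e-3, R_o=27e-3),
            DWRGeometry(R_i=10e-3, R4=14.5e-3, R5=15.5e-3, R_o=21e-3),
        ],
        ids=["default", "narrow", "small"],
    )
    def test_g1_agreement_across_geometries(self, geo):
        m = build_mesh(geo, 16)
        sol = solve_field(m, 1e6, 0.0, (WATER, None))
        K_i, _ = compute_drags(sol, m, geo, (WATER, None))
        assert (K_i / sol.eta_s).real == pytest.approx(
            g1_coefficient(geo), rel=1e-2
        )

    def test_second_order_refinement(self, geom):
        """|K(h) - K(h/2)| shrinks ~4x per halving for both drags in the
        interface-dominated regime (Richardson)."""
        omega = np.pi
        Bo = 1e4 * np.exp(-1j * np.pi / 4)
        vals = {}
        for res in (8, 16, 32):
            m = build_mesh(geom, res)
            sol = solve_field(m, Bo, omega, (WATER, None))
            vals[res] = compute_drags(sol, m, geom, (WATER, None))
        for q in (0, 1):
            e1 = abs(vals[8][q] - vals[16][q])
            e2 = abs(vals[16][q] - vals[32][q])
            assert 3.0 < e1 / e2 < 5.0

    def test_interfacial_drag_monotone_in_bo(self, geom, mesh16):
        omega = np.pi
        k_prev = 0.0
        for bo in (1e-2, 1e0, 1e2, 1e4, 1e6):
            sol = solve_field(mesh16, bo, omega, (WATER, None))
            K_i, _ = compute_drags(sol, mesh16, geom, (WATER, None))
            assert abs(K_i) >= k_prev
            k_prev = abs(K_i)

    def test_viscous_interface_low_frequency_real_drags(self, geom, mesh16):
        """Purely viscous interface, omega -> 0: drag phases vanish.

        With fluid inertia off the steady problem is exactly real; with it
        on the phases shrink linearly with omega.
        """
        sol = solve_field(
            mesh16, 50.0, 1e-3, (WATER, None), include_fluid_inertia=False
        )
        K_i, K_b = compute_drags(sol, mesh16, geom, (WATER, None))
        assert abs(np.angle(K_i)) < 1e-12
        assert abs(np.angle(K_b)) < 1e-12
        assert K_i.real > 0 and K_b.real > 0
        phases = []
        for om in (1e-2, 1e-3):
            s = solve_field(mesh16, 50.0, om, (WATER, None))
            ki, kb = compute_drags(s, mesh16, geom, (WATER, None))
            phases.append(abs(np.angle(ki)) + abs(np.angle(kb)))
        assert phases[1] < 0.2 * phases[0]  # ~linear decay toward zero

    def test_surface_quadrature_route_consistent(self, geom):
        """The direct wetted-surface traction quadrature (diagnostic route)
        agrees with the momentum-balance contour within a few percent."""
        m = build_mesh(geom, 32)
        sol = solve_field(m, 0.0, 0.0, (WATER, None))
        _, K_b = compute_drags(sol, m, geom, (WATER, None))
        K_face = wetted_surface_torque(sol, m, (WATER, None))
        assert K_face.real == pytest.approx(K_b.real, rel=0.03)


class TestTwoPhase:
    def test_upper_phase_adds_drag(self, geom):
        m1 = build_mesh(geom, 12)
        m2 = build_mesh(geom, 12, two_phase=True)
        heavy_top = AIR.__class__(eta=5e-4, rho=800.0)
        sol1 = solve_field(m1, 10.0, np.pi, (WATER, None))
        sol2 = solve_field(m2, 10.0, np.pi, (WATER, heavy_top))
        k1 = sum(compute_drags(sol1, m1, geom, (WATER, None)))
        k2 = sum(compute_drags(sol2, m2, geom, (WATER, heavy_top)))
        assert k2.real > k1.real

    def test_air_top_is_negligible(self, geom):
        # compare against the uncorrected single-phase solve (the two-phase
        # path skips the corner subtraction)
        m1 = build_mesh(geom, 12)
        m2 = build_mesh(geom, 12, two_phase=True)
        sol1 = solve_field(m1, 10.0, np.pi, (WATER, None), corner_correction=False)
        sol2 = solve_field(m2, 10.0, np.pi, (WATER, AIR))
        k1 = sum(compute_drags(sol1, m1, geom, (WATER, None)))
        k2 = sum(compute_drags(sol2, m2, geom, (WATER, AIR)))
        assert abs(k2 - k1) / abs(k1) < 0.03

    def test_zero_viscosity_top_matches_single_phase(self, geom):
        from rheoref.geometry import FluidPhase
        m1 = build_mesh(geom, 12)
        m2 = build_mesh(geom, 12, two_phase=True)
        sol1 = solve_field(m1, 10.0, np.pi, (WATER, None), corner_correction=False)
        sol2 = solve_field(m2, 10.0, np.pi, (WATER, FluidPhase(eta=0.0, rho=1.2)))
        k1 = compute_drags(sol1, m1, geom, (WATER, None))
        k2 = compute_drags(sol2, m2, geom, (WATER, FluidPhase(eta=0.0, rho=1.2)))
        assert abs(k1[0] - k2[0]) / abs(k1[0]) < 1e-10
        assert abs(k1[1] - k2[1]) / abs(k1[1]) < 1e-10
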