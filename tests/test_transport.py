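"""Balloon flux, FEM operators, and transient solver verification."""

import numpy as np
import pytest
from scipy.integrate import quad

from meshlift.mesh import MURAL, PERIVASCULAR, TriMesh, build_annulus_mesh
from meshlift.transport import (
    SolverSettings,
    TransportParameters,
    assemble_operators,
    balloon_flux,
    binding_relaxation,
    bound_equilibrium,
    released_mass_per_area,
    solve_steady_diffusion,
    solve_transient,
)


class TestParameters:
    def test_derived_rates_hold_exactly(self, params):
        assert params.k_a == params.D_w * params.Da / (params.B_M * params.W**2)
        assert params.k_d_rate == params.k_a * params.K_d

    def test_binding_disabled_at_zero_damkoehler(self):
        p = TransportParameters(Da=0.0)
        assert p.k_a == 0.0 and p.k_d_rate == 0.0

    @pytest.mark.parametrize("bad", [{"D_w": 0.0}, {"B_M": -1.0}, {"t_0": 0.0}, {"Da": -1.0}])
    def test_nonphysical_values_rejected(self, bad):
        with pytest.raises(ValueError):
            TransportParameters(**bad)


class TestBalloonFlux:
    def test_zero_after_deflation(self, params):
        assert balloon_flux(params.t_0 + 1.0, params) == 0.0
        assert balloon_flux(params.t_0, params) > 0.0

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            balloon_flux(-1.0, params)

    def test_nonnegative_and_monotone_during_inflation(self, params):
        t = np.linspace(0.0, params.t_0, 2000)
        j = balloon_flux(t, params)
        assert np.all(j >= 0)
        assert np.all(np.diff(j) <= 0)

    def test_cumulative_release_matches_quadrature(self, params):
        """The closed-form integral of the flux equals numerical quadrature."""
        num, _ = quad(lambda t: balloon_flux(t, params), 0.0, params.t_0)
        assert released_mass_per_area(params.t_0, params) == pytest.approx(num, rel=1e-10)
        # nothing more is released after deflation
        assert released_mass_per_area(3600.0, params) == released_mass_per_area(
            params.t_0, params
        )


class TestOperators:
    def test_stiffness_annihilates_constants(self, small_mesh):
        ops = assemble_operators(small_mesh)
        assert np.abs(ops.stiffness @ np.ones(small_mesh.n_nodes)).max() < 1e-12

    def test_mass_sum_is_domain_area(self, geometry, small_mesh):
        ops = assemble_operators(small_mesh)
        assert ops.mass.sum() == pytest.approx(geometry.area, rel=5e-3)
        assert np.all(ops.mass_lumped > 0)

    def test_mural_boundary_mass_is_inner_perimeter(self, geometry, small_mesh):
        ops = assemble_operators(small_mesh)
        assert ops.mural_mass_lumped.sum() == pytest.approx(
            2 * np.pi * geometry.R, rel=5e-3
        )
        # supported only on mural nodes
        assert np.all(ops.mural_mass_lumped[small_mesh.boundary_tag != MURAL] == 0)

    def test_untagged_mesh_rejected(self):
        m = TriMesh(
            node_coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
            elements=np.array([[0, 1, 2]]),
            boundary_tag=np.zeros(3, dtype=np.int8),
        )
        with pytest.raises(ValueError):
            assemble_operators(m)


class TestSolver:
    def test_zero_flux_zero_ic_stays_zero(self, small_mesh, params):
        fld = solve_transient(
            small_mesh, params, SolverSettings(t_end=100.0), flux_fn=lambda t: 0.0
        )
        assert np.all(fld.C == 0.0) and np.all(fld.B == 0.0)

    def test_steady_profile_matches_annular_log_solution(self, geometry):
        """Binding disabled, constant unit flux, sink outer wall: the steady
        state is C(r) = (q R / D) ln((R+W)/r); P1 solution within 1% in L2."""
        m = build_annulus_mesh(geometry, 1000, seed=2)
        p = TransportParameters(Da=0.0)
        C = solve_steady_diffusion(m, p.D_w, 1.0)
        r = np.hypot(m.node_coords[:, 0], m.node_coords[:, 1])
        exact = geometry.R / p.D_w * np.log(geometry.outer_radius / r)
        err = np.sqrt(np.mean((C - exact) ** 2)) / np.sqrt(np.mean(exact**2))
        assert err < 0.01

    def test_wellmixed_binding_matches_scalar_ode(self, geometry, params):
        """With the free level clamped, bound drug follows the closed-form
        relaxation to the Langmuir equilibrium with rate k_a C + k_d."""
        m = build_annulus_mesh(geometry, 30, seed=0)
        C0 = 0.1
        for t_end in (2.0, 10.0):
            fld = solve_transient(
                m, params, SolverSettings(t_end=t_end),
                flux_fn=lambda t: 0.0, C0=C0, outer_bc="noflux", clamp_free=True,
            )
            exact = binding_relaxation(C0, t_end, params)
            assert np.abs(fld.B - exact).max() / exact < 1e-3
        # equilibrium limit
        beq = bound_equilibrium(C0, params)
        assert beq == pytest.approx(params.B_M * C0 / (params.K_d + C0))

    def test_balloon_fields_physical(self, small_mesh, params, solved_small):
        fld = solved_small
        eps = 1e-6  # solver absolute tolerance
        assert fld.C.min() >= -eps
        assert fld.B.min() >= -eps and fld.B.max() <= params.B_M + eps
        # perfect sink: C vanishes on the perivascular boundary
        assert np.all(fld.C[small_mesh.boundary_tag == PERIVASCULAR] == 0.0)
        assert fld.C.max() > 0 and fld.B.max() > 0

    def test_mass_balance(self, geometry, params):
        """Total drug in tissue equals cumulative mural influx minus sink
        outflow to within 0.1% (discrete balance)."""
        m = build_annulus_mesh(geometry, 200, seed=5)
        ops = assemble_operators(m)
        t_end = 600.0
        t_eval = np.linspace(0.0, t_end, 601)
        fld, times, C_traj, B_traj = solve_transient(
            m, params, SolverSettings(t_end=t_end), t_eval=t_eval
        )
        total = ops.mass_lumped @ (fld.C + fld.B)
        injected = released_mass_per_area(t_end, params) * ops.mural_mass_lumped.sum()
        # discrete sink outflow: stiffness residual at Dirichlet rows
        periv = m.boundary_tag == PERIVASCULAR
        out_rate = np.array(
            [-(params.D_w * (ops.stiffness @ C))[periv].sum() for C in C_traj]
        )
        outflow = np.trapezoid(out_rate, times)
        assert total == pytest.approx(injected - outflow, rel=1e-3)

    def test_grid_convergence_and_symmetry(self, geometry, params):
        """Consecutive-level L2 differences shrink (the premise the surrogate
        exploits) and angular variance at the mural ring shrinks from L0 to L3."""
        from meshlift.mesh import MURAL, build_hierarchy, common_nodes

        hierarchy = build_hierarchy(geometry, 300, 3, seed=7)
        flds = [solve_transient(m, params, SolverSettings()) for m in hierarchy]
        diffs = []
        for lo, hi in zip(flds[:-1], flds[1:]):
            pairs = common_nodes(lo.mesh, hi.mesh)
            diffs.append(
                np.sqrt(np.mean((lo.C[pairs[:, 0]] - hi.C[pairs[:, 1]]) ** 2))
            )
        assert diffs[0] > diffs[1] > diffs[2]
        var = [np.var(f.C[f.mesh.boundary_tag == MURAL]) for f in flds]
        assert var[-1] < var[0]
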