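"""Moving-grid FEM solver: assembly oracles, fixed point, mode decay,
symmetry reduction, maximum principle, blow-up signalling."""

import numpy as np
import pytest

import morphocontract as mc
from morphocontract.solver import BANDWIDTH, NFIELDS, FIELD_NAMES


def tiny_params(params):
    """A reduced parameter set with every kinetic and mechanical coupling
    switched off (pure diffusion in c); bypasses positivity validation on
    purpose — it is a numerical reduction, not a physical state."""
    return params.replace(
        k_c=0.0, delta_c=0.0, r_F=0.0, k_F=0.0, delta_N=0.0, delta_M=0.0,
        k_rho=0.0, delta_rho=0.0, zeta=0.0, xi=0.0, chi_F=0.0, D_F=0.0,
        E=0.0, q=0.0)


def field_block(dense, m, f_row, f_col):
    idx_r = NFIELDS * np.arange(m) + f_row
    idx_c = NFIELDS * np.arange(m) + f_col
    return dense[np.ix_(idx_r, idx_c)]


class TestAssembly:
    def test_equilibrium_is_exact_root_of_step_system(self, params, eq):
        """Plugging the equilibrium into the assembled system returns the
        equilibrium: the nonlinear residual vanishes to assembly tolerance."""
        mesh = mc.MeshState.uniform(1.0, 30)
        f = mc.FieldState.equilibrium(31, eq)
        cfg = mc.SolverConfig(boundary_mode="half")
        sys = mc.assemble_step_system(f, mesh, params, 0.5, (f, mesh), cfg, eq)
        sol = sys.solve()
        got = mc.FieldState.from_vector(sol)
        for name in FIELD_NAMES:
            a = getattr(got, name)
            b = getattr(f, name)
            scale = max(np.abs(b).max(), 1e-30)
            assert np.max(np.abs(a - b)) / scale < 1e-12, name

    def test_pure_diffusion_matches_hand_assembled_heat_system(self, params,
                                                               eq):
        """With all kinetics and velocity zeroed, the c-block equals the
        standard lumped FEM backward-Euler heat system, hand-assembled on
        3 elements (4 nodes)."""
        p = tiny_params(params)
        mesh = mc.MeshState.uniform(1.0, 3)
        m = 4
        h = 1.0 / 3.0
        dt = 0.01
        f = mc.FieldState.equilibrium(m, eq)
        f.c = np.array([0.0, 0.3, 0.1, 0.0])
        cfg = mc.SolverConfig(boundary_mode="full")
        sys = mc.assemble_step_system(f, mesh, p, dt, (f, mesh), cfg, eq)
        dense = sys.to_dense()
        cc = field_block(dense, m, 0, 0)
        # hand assembly: lumped masses [h/2, h, h, h/2]/dt + D_c/h tridiag
        D = p.D_c
        expect = np.array([
            [1.0, 0.0, 0.0, 0.0],                     # Dirichlet row
            [-D / h, h / dt + 2 * D / h, -D / h, 0.0],
            [0.0, -D / h, h / dt + 2 * D / h, -D / h],
            [0.0, 0.0, 0.0, 1.0],                     # Dirichlet row
        ])
        assert np.allclose(cc, expect, rtol=1e-13, atol=1e-15)
        # rhs of the interior c rows is lumped old mass / dt
        rhs_c = sys.rhs[0::NFIELDS]
        assert rhs_c[1] == pytest.approx(h / dt * 0.3, rel=1e-13)
        assert rhs_c[2] == pytest.approx(h / dt * 0.1, rel=1e-13)

    def test_interior_stencil_symbol_matches_von_neumann_matrix(self, params,
                                                                eq):
        """DFT symbol of the interior rows of the assembled step matrix at
        the equilibrium equals the Von Neumann mode matrix, mode by mode.

        On a uniform mesh, dividing each interior row by the lumped mass h
        turns the FEM system into the finite-difference stencil; applying
        the discrete Fourier vector yields (1/dt) I + C(beta) (the velocity
        row additionally carries the rho_t factor).  A documented subset of
        entries lives in the Picard iteration rather than the matrix: the
        couplings whose coefficients are frozen at the previous iterate
        (differentiation, secretion and chemotaxis cross-terms, the body
        force), the logistic reaction of N (its frozen coefficient cancels
        delta_N exactly at the equilibrium), and half of the quadratic
        collagen decay."""
        p, N_bar, rho_bar = params, eq.N_bar, eq.rho_bar
        n = 64
        h = 1.0 / n
        dt = 0.125
        mesh = mc.MeshState.uniform(1.0, n)
        f = mc.FieldState.equilibrium(n + 1, eq)
        cfg = mc.SolverConfig(boundary_mode="half")
        sys = mc.assemble_step_system(f, mesh, p, dt, (f, mesh), cfg, eq)
        dense = sys.to_dense()
        mid = n // 2
        # entries realized through Picard coefficient updates, not the matrix
        # (secretion, differentiation, chemotaxis, crowding, body force)
        frozen = {(1, 0), (2, 0), (2, 1), (3, 0), (3, 1), (4, 1)}
        corrections = {
            # logistic N reaction: frozen coefficient equals delta_N at eq
            (2, 2): -(p.r_F * p.kappa_F * N_bar ** (1 + p.q)
                      - p.q * p.delta_N),
            # rho^2 decay linearized by freezing one factor: half appears
            (3, 3): -p.delta_rho * N_bar * rho_bar,
        }
        for beta in (1, 5, 13):
            C = mc.assemble_discrete(params, eq,
                                     mc.DiscreteMode(beta, h, n)).A
            # variable order of C is (c, M, N, rho, v, eps); solver order is
            # (c, N, M, rho, v, eps)
            perm = np.array([0, 2, 1, 3, 4, 5])
            phase = np.exp(-2j * np.pi * beta * h * np.arange(n + 1))
            for fr in range(6):
                row = dense[NFIELDS * mid + perm[fr]]
                w = params.rho_t if fr == 4 else 1.0
                for fc in range(6):
                    if (fr, fc) in frozen:
                        continue
                    symbol = (row[perm[fc]::NFIELDS] @ phase) \
                        / (h * phase[mid])
                    expect = C[fr, fc] + corrections.get((fr, fc), 0.0) \
                        + (1.0 / dt if fr == fc else 0.0)
                    expect = w * expect
                    scale = max(abs(expect), np.abs(C).max() * 1e-8)
                    assert abs(symbol - expect) / scale < 1e-9, \
                        (beta, fr, fc, symbol, expect)

    def test_bandwidth_is_respected(self, params, eq):
        mesh = mc.MeshState.uniform(1.0, 12)
        f = mc.FieldState.equilibrium(13, eq)
        cfg = mc.SolverConfig(boundary_mode="half")
        sys = mc.assemble_step_system(f, mesh, params, 0.5, (f, mesh), cfg, eq)
        dense = sys.to_dense()
        ii, jj = np.nonzero(dense)
        assert np.max(np.abs(ii - jj)) <= BANDWIDTH


class TestAdvance:
    def test_equilibrium_fixed_point_one_iteration(self, params, eq):
        mesh = mc.MeshState.uniform(1.0, 50)
        f = mc.FieldState.equilibrium(51, eq)
        cfg = mc.SolverConfig(boundary_mode="half")
        f2, mesh2, info = mc.advance(f, mesh, cfg, params, eq)
        assert info.converged and info.iterations == 1
        assert np.array_equal(mesh2.nodes, mesh.nodes)
        for name in FIELD_NAMES:
            scale = max(np.abs(getattr(f, name)).max(), 1e-30)
            assert np.max(np.abs(getattr(f2, name) - getattr(f, name))) \
                / scale < 1e-12

    @pytest.mark.parametrize("dt", [0.5, 5.0])
    def test_equilibrium_invariant_over_100_steps(self, params, eq, dt):
        """Backward Euler keeps the equilibrium for any step size (the
        A-stability property of the implicit scheme)."""
        mesh = mc.MeshState.uniform(1.0, 40)
        f = mc.FieldState.equilibrium(41, eq)
        cfg = mc.SolverConfig(dt_schedule=((0.0, dt),), boundary_mode="half")
        for _ in range(100):
            f, mesh, _ = mc.advance(f, mesh, cfg, params, eq)
        assert np.max(np.abs(f.N - eq.N_bar)) / eq.N_bar < 1e-10
        assert np.max(np.abs(f.rho - eq.rho_bar)) / eq.rho_bar < 1e-10
        assert np.max(np.abs(f.c)) < 1e-10
        assert np.max(np.abs(f.M)) < 1e-10
        assert np.max(np.abs(f.v)) < 1e-10
        assert np.max(np.abs(f.eps)) < 1e-10

    def test_signaling_mode_decays_at_continuous_rate(self, params, eq):
        """A small half-wave c perturbation decays at the analytic rate of
        the signaling eigenvalue within 10%."""
        n = 200
        mesh = mc.MeshState.uniform(1.0, n)
        f = mc.FieldState.equilibrium(n + 1, eq)
        f.c = f.c + 1e-12 * np.sin(np.pi * mesh.nodes)
        cfg = mc.SolverConfig(dt_schedule=((0.0, 0.01),),
                              boundary_mode="full")
        c0 = np.abs(f.c).max()
        steps = 20
        for _ in range(steps):
            f, mesh, _ = mc.advance(f, mesh, cfg, params, eq)
        rate = -np.log(np.abs(f.c).max() / c0) / (steps * 0.01)
        lam = mc.eigenvalues_continuous(
            mc.assemble_continuous(params, eq,
                                   mc.FourierMode(1, omega_len=2.0)))[0].real
        assert abs(rate - lam) / lam < 0.10

    def test_mesh_moves_left_under_negative_velocity(self, params, eq):
        """With myofibroblast traction concentrated near the left boundary,
        v becomes negative in the bulk and interior nodes move left."""
        n = 100
        mesh = mc.MeshState.uniform(1.0, n)
        f = mc.FieldState.equilibrium(n + 1, eq)
        f.M = 50.0 * np.exp(-((mesh.nodes - 0.15) / 0.05) ** 2)
        cfg = mc.SolverConfig(dt_schedule=((0.0, 0.05),),
                              boundary_mode="half")
        f2, mesh2, _ = mc.advance(f, mesh, cfg, params, eq)
        bulk = mesh.nodes > 0.3
        assert np.mean(f2.v[bulk] <= 0) > 0.95
        assert np.all(mesh2.nodes[1:-1][bulk[1:-1]]
                      <= mesh.nodes[1:-1][bulk[1:-1]])
        assert mesh2.nodes[0] == 0.0 and mesh2.nodes[-1] == 1.0
        # displacement bookkeeping follows the node update rule
        assert np.allclose(mesh2.u, 0.05 * f2.v, rtol=0, atol=1e-15)

    def test_half_domain_equals_mirrored_full_domain(self, params, eq):
        """A symmetric full-domain run restricted to the left half agrees
        with the half-domain run using the symmetry boundary (densities
        mirror evenly, velocity oddly)."""
        n = 60
        scn = mc.PerturbationScenario(k=2)
        mesh_h = mc.MeshState.uniform(1.0, n)
        f_h = mc.make_perturbation_profile(scn, mesh_h, eq)
        mesh_f = mc.MeshState.uniform(2.0, 2 * n)
        f_f = mc.FieldState.equilibrium(2 * n + 1, eq)
        for name in ("c", "N", "M", "rho", "eps"):
            half = getattr(f_h, name)
            setattr(f_f, name, np.concatenate([half, half[-2::-1]]))
        f_f.v = np.concatenate([f_h.v, -f_h.v[-2::-1]])
        cfg_h = mc.SolverConfig(dt_schedule=((0.0, 0.05),),
                                boundary_mode="half")
        cfg_f = cfg_h.replace(boundary_mode="full")
        for _ in range(10):
            f_h, mesh_h, _ = mc.advance(f_h, mesh_h, cfg_h, params, eq)
            f_f, mesh_f, _ = mc.advance(f_f, mesh_f, cfg_f, params, eq)
        for name in FIELD_NAMES:
            a = getattr(f_h, name)
            b = getattr(f_f, name)[:n + 1]
            scale = max(np.abs(a).max(), 1e-30)
            assert np.max(np.abs(a - b)) / scale < 1e-6, name
        assert np.max(np.abs(mesh_h.nodes - mesh_f.nodes[:n + 1])) < 1e-9

    def test_lumped_diffusion_satisfies_maximum_principle(self, params, eq,
                                                          rng):
        """Pure-diffusion reduction with mass lumping: new nodal values stay
        within the old range (discrete maximum principle); the consistent
        mass matrix violates it for large dt/h^2."""
        p = tiny_params(params)
        n = 20
        mesh = mc.MeshState.uniform(1.0, n)
        f = mc.FieldState.equilibrium(n + 1, eq)
        f.c = rng.uniform(0.0, 1.0, n + 1)
        f.c[0] = f.c[-1] = 0.0
        cfg = mc.SolverConfig(dt_schedule=((0.0, 10.0),),
                              boundary_mode="full", lumping=True)
        g = f.copy()
        for _ in range(5):
            g, mesh, _ = mc.advance(g, mesh, cfg, p, eq)
            assert g.c.min() >= -1e-13
            assert g.c.max() <= f.c.max() + 1e-13

    def test_blow_up_signalled_with_diagnostics(self, params, eq):
        """A nonphysical state (negative collagen at huge magnitude) breaks
        the step; the solver reports blow-up instead of returning NaN."""
        n = 30
        mesh = mc.MeshState.uniform(1.0, n)
        f = mc.FieldState.equilibrium(n + 1, eq)
        f.v = 1e6 * np.sin(np.pi * mesh.nodes)   # one step tangles the mesh
        cfg = mc.SolverConfig(dt_schedule=((0.0, 0.5),),
                              boundary_mode="full")
        with pytest.raises(mc.BlowUpError) as exc:
            mc.advance(f, mesh, cfg, params, eq)
        assert "tangling" in str(exc.value)


class TestRelativeSurfaceArea:
    def test_definition_and_error_cases(self):
        mesh = mc.MeshState.uniform(10.0, 10)
        d0 = mesh.nodes[7] - mesh.nodes[3]
        assert mc.relative_surface_area(mesh, (3, 7), d0) == 1.0
        with pytest.raises(ValueError):           # crossed (coincident) markers
            mc.relative_surface_area(mesh, (5, 5), d0)

    def test_stationary_equilibrium_keeps_rsaw_one(self, params, eq):
        mesh = mc.MeshState.uniform(1.0, 40)
        f = mc.FieldState.equilibrium(41, eq)
        cfg = mc.SolverConfig(dt_schedule=((0.0, 1.0),), boundary_mode="half")
        traj = mc.simulate(f, mesh, cfg, params, eq, 5.0, markers=(10, 30))
        assert np.allclose(traj.history["rsaw"], 1.0, rtol=0, atol=1e-14)


class TestSimulate:
    def test_records_history_and_completes(self, params, eq):
        scn = mc.PerturbationScenario(k=1)
        mesh = mc.MeshState.uniform(1.0, 50)
        f = mc.make_perturbation_profile(scn, mesh, eq)
        cfg = mc.SolverConfig(dt_schedule=((0.0, 0.5),), boundary_mode="half")
        traj = mc.simulate(f, mesh, cfg, params, eq, 10.0)
        assert traj.termination == "completed"
        frame = traj.frame()
        assert frame["t"].iloc[-1] == pytest.approx(10.0)
        assert (frame["picard_iterations"].iloc[1:] >= 1).all()
        # the mechanical perturbation equilibrates within days (high
        # viscosity); a small quasi-static residual velocity remains while
        # the density fields keep rearranging
        assert abs(frame["v_max"].iloc[-1]) < 0.05 * frame["v_max"].iloc[0]

    def test_event_reset_is_applied_at_exact_time(self, params, eq):
        scn = mc.PerturbationScenario(k=1)
        mesh = mc.MeshState.uniform(1.0, 30)
        f = mc.make_perturbation_profile(scn, mesh, eq)
        cfg = mc.SolverConfig(dt_schedule=((0.0, 0.4),), boundary_mode="half")

        def reset_c(fields, mesh_):
            out = fields.copy()
            out.c[:] = 0.0
            return out

        traj = mc.simulate(f, mesh, cfg, params, eq, 3.0,
                           events=[(1.0, reset_c)])
        frame = traj.frame()
        i = int(np.argmin(np.abs(frame["t"].to_numpy() - 1.0)))
        assert frame["t"].iloc[i] == pytest.approx(1.0)
        assert frame["c_max"].iloc[i] == 0.0
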