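"""Buffered PNP solver: initialization, buffering, assembly, conservation,
Debye physics, and the dense brute-force oracle for one coupled step."""

import numpy as np
import pytest

from nanodyad.constants import (
    CONSTANTS,
    IonSpecies,
    buffer_equilibrium,
    default_buffers,
    default_species,
    thermal_voltage,
)
from nanodyad.membrane import ALWAYS_CLOSED, ALWAYS_OPEN, ChannelSpec, mouth_state
from nanodyad.mesh import (
    OMEGA_I,
    DomainGeometry,
    UnitPlacement,
    build_mesh,
)
from nanodyad.solver import (
    ConfigurationError,
    SolverConfig,
    SolverError,
    Stepper,
    assemble_coupled_system,
    buffering_step,
    charge_density,
    init_state,
    solve_step,
    total_amounts,
)

KCL = [
    IonSpecies("K", +1, 2.03e6, 2.03e6, 100.0, 100.0),
    IonSpecies("Cl", -1, 2.03e6, 2.03e6, 100.0, 100.0),
]


def small_box_2d(n=16, L=16.0):
    """Membrane-free 2D box (single subdomain)."""
    g = DomainGeometry(Le=0.0, Lm=0.0, Li=L, Ly=L, Lz=1.0, dims=2)
    return g, build_mesh(g, [], fine_dx=L / n, fine_dyz=L / n, uniform=True)


def small_dyad_3d():
    g = DomainGeometry(Ly=60.0, Lz=60.0)
    pls = [UnitPlacement("K", 30.0, 30.0, "main")]
    mesh = build_mesh(g, pls, fine_dx=0.5, fine_dyz=4.0, max_spacing=64.0)
    return g, mesh, pls


class TestInitState:
    def test_background_charge_neutralizes(self):
        _, mesh, _ = small_dyad_3d()
        state = init_state(default_species(), default_buffers(), mesh)
        rho = charge_density(state)
        assert np.abs(rho).max() == pytest.approx(0.0, abs=1e-9)
        sub = mesh.subdomain.ravel()
        extra = sub == 0
        intra = sub == OMEGA_I
        # extracellular column is electroneutral on its own
        assert np.abs(state.rho0[extra]).max() == pytest.approx(0.0, abs=1e-8)
        # intracellular background charge balances ions + bound buffer
        b_hi = buffer_equilibrium(1e-4, default_buffers()[0])
        b_lo = buffer_equilibrium(1e-4, default_buffers()[1])
        expected = -CONSTANTS.F * (12 + 125 + 2 * (1e-4 + b_hi + b_lo) - 15)
        assert state.rho0[intra][0] == pytest.approx(expected, rel=1e-12)

    def test_charge_density_linearity(self):
        _, mesh, _ = small_dyad_3d()
        state = init_state(default_species(), default_buffers(), mesh)
        cell = np.argmax(mesh.subdomain.ravel() == OMEGA_I)
        state.c[state.species_index("K")][cell] += 1.0
        rho = charge_density(state)
        assert rho[cell] == pytest.approx(CONSTANTS.F, rel=1e-12)


class TestBufferingStep:
    def test_equilibrium_is_fixed_point(self):
        _, mesh, _ = small_dyad_3d()
        state = init_state(default_species(), default_buffers(), mesh)
        intra = mesh.subdomain.ravel() == OMEGA_I
        c_tilde, b_new, Bb = buffering_step(state, 1e-3, intra)
        assert np.allclose(c_tilde, state.c, atol=1e-15)
        assert np.allclose(b_new, state.b, atol=1e-15)

    def test_forward_euler_rate(self):
        # c = 1e-4 mM, b = 0, high-affinity buffer: JB = 2e-3 mM/ms
        _, mesh, _ = small_dyad_3d()
        state = init_state(default_species(), [default_buffers()[0]], mesh)
        intra = mesh.subdomain.ravel() == OMEGA_I
        state.b[0][:] = 0.0
        k = state.species_index("Ca")
        c_tilde, b_new, Bb = buffering_step(state, 1e-3, intra)
        cell = np.argmax(intra)
        assert Bb[k][cell] == pytest.approx(2e-3, rel=1e-12)
        assert b_new[0][cell] == pytest.approx(2e-6, rel=1e-12)
        assert state.c[k][cell] - c_tilde[k][cell] == pytest.approx(2e-6, rel=1e-12)

    def test_free_plus_bound_conserved(self):
        _, mesh, _ = small_dyad_3d()
        state = init_state(default_species(), default_buffers(), mesh)
        intra = mesh.subdomain.ravel() == OMEGA_I
        k = state.species_index("Ca")
        state.c[k][intra] *= 5.0  # off equilibrium
        for substeps in (1, 7):
            c_tilde, b_new, _ = buffering_step(state, 1e-3, intra, substeps)
            before = state.c[k] + state.b.sum(axis=0)
            after = c_tilde[k] + b_new.sum(axis=0)
            assert np.abs(after - before).max() < 1e-14

    def test_overshoot_raises(self):
        _, mesh, _ = small_dyad_3d()
        state = init_state(default_species(), default_buffers(), mesh)
        intra = mesh.subdomain.ravel() == OMEGA_I
        k = state.species_index("Ca")
        state.c[k][intra] = 50.0  # kon*c*dt >> 1
        with pytest.raises(SolverError, match="buffer"):
            buffering_step(state, 1e-2, intra)


class TestCoupledStep:
    def test_uniform_neutral_state_is_fixed_point(self):
        _, mesh, pls = small_dyad_3d()
        species, buffers = default_species(), default_buffers()
        state = init_state(species, buffers, mesh)
        units = [ChannelSpec("K", 5e9, pls[0], ALWAYS_CLOSED)]
        st = Stepper(mesh, species, buffers, units, SolverConfig(dt=1e-2))
        new = st.step(state)
        assert np.abs(new.phi).max() < 1e-7
        assert np.abs(new.c - state.c).max() < 1e-8

    def test_mass_conserved_with_closed_units(self):
        _, mesh, pls = small_dyad_3d()
        species, buffers = default_species(), default_buffers()
        state = init_state(species, buffers, mesh)
        # non-trivial state: perturb K+ in a few interior cells
        intra_cells = np.where(mesh.subdomain.ravel() == OMEGA_I)[0]
        state.c[state.species_index("K")][intra_cells[:4]] += 5.0
        units = [ChannelSpec("K", 5e9, pls[0], ALWAYS_CLOSED)]
        st = Stepper(mesh, species, buffers, units, SolverConfig(dt=1e-3))
        before = total_amounts(state, mesh)
        s = state
        for _ in range(20):
            s = st.step(s)
        after = total_amounts(s, mesh)
        for name in before:
            assert abs(after[name] - before[name]) <= 1e-10 * abs(before[name])

    def test_channel_moves_mass_between_compartments_only(self):
        # open unit: per-species totals still conserved (mouth fluxes cancel)
        _, mesh, pls = small_dyad_3d()
        species, buffers = default_species(), default_buffers()
        state = init_state(species, buffers, mesh)
        units = [ChannelSpec("K", 5e9, pls[0], ALWAYS_OPEN)]
        st = Stepper(mesh, species, buffers, units, SolverConfig(dt=1e-2))
        before = total_amounts(state, mesh)
        s = state
        for _ in range(10):
            s = st.step(s)
        after = total_amounts(s, mesh)
        for name in before:
            assert abs(after[name] - before[name]) <= 1e-10 * abs(before[name])
        # and K+ has genuinely crossed the membrane
        sub = mesh.subdomain.ravel()
        V = mesh.cell_volumes.ravel()
        k = s.species_index("K")
        intra_K = float(s.c[k][sub == OMEGA_I] @ V[sub == OMEGA_I])
        intra_K0 = float(state.c[k][sub == OMEGA_I] @ V[sub == OMEGA_I])
        assert intra_K < intra_K0

    def test_missing_potential_anchor_rejected(self):
        _, mesh, _ = small_dyad_3d()
        with pytest.raises(ConfigurationError, match="Dirichlet"):
            Stepper(mesh, default_species(), [], [],
                    SolverConfig(dt=1e-3, phi_dirichlet={}))

    def test_spec_wrappers_match_stepper(self):
        _, mesh, pls = small_dyad_3d()
        species, buffers = default_species(), default_buffers()
        state = init_state(species, buffers, mesh)
        cfg = SolverConfig(dt=1e-2)
        units = [ChannelSpec("K", 5e9, pls[0], ALWAYS_OPEN)]
        intra = mesh.subdomain.ravel() == OMEGA_I
        c_tilde, b_new, _ = buffering_step(state, cfg.dt, intra)
        system = assemble_coupled_system(state, c_tilde, mesh, units, cfg,
                                         b_new=b_new)
        new = solve_step(system, cfg)
        st = Stepper(mesh, species, buffers, units, cfg)
        ref = st.step(state)
        # same discrete solution up to linear-solver rounding
        assert np.allclose(new.phi, ref.phi, atol=1e-6)
        assert np.allclose(new.c, ref.c, atol=1e-9)


class TestDenseOracle:
    def test_coupled_step_matches_dense_assembly_1d(self):
        """One implicit step on a 16-cell 1D two-ion problem against an
        independently written dense assembly of the same discrete equations."""
        n = 16
        L = 8.0
        g = DomainGeometry(Le=0.0, Lm=0.0, Li=L, Ly=1.0, Lz=1.0, dims=2)
        mesh = build_mesh(g, [], fine_dx=L / n, fine_dyz=1.0, uniform=True)
        assert mesh.shape == (n, 1, 1)
        species = KCL
        state = init_state(species, [], mesh, electroneutral=False)
        # non-uniform start: linear K+ ramp
        state.c[0] = 100.0 + np.linspace(-5, 5, n)
        cfg = SolverConfig(dt=1e-6, phi_dirichlet={"x-": 0.0})
        st = Stepper(mesh, species, [], [], cfg)
        new = st.step(state)

        # --- dense oracle -------------------------------------------------
        h = L / n
        A_face = 1.0  # 1 nm x 1 nm cross-section
        V = h * 1.0
        vt = thermal_voltage(CONSTANTS)
        eps = 80.0 * CONSTANTS.eps0
        F = CONSTANTS.F
        D = 2.03e6
        z = np.array([1, -1])
        nunk = n + 2 * n
        A = np.zeros((nunk, nunk))
        b = np.zeros(nunk)
        Tphi = eps * A_face / h
        Td = D * A_face / h
        for i in range(n):
            # Poisson row i
            for j, dsign in ((i - 1, +1), (i + 1, +1)):
                if 0 <= j < n:
                    A[i, j] += Tphi
                    A[i, i] -= Tphi
            if i == 0:  # Dirichlet phi = 0 at the left wall (half spacing)
                A[i, i] -= eps * A_face / (h / 2)
            for k in range(2):
                A[i, n + k * n + i] += V * F * z[k]
            b[i] = -V * state.rho0[i]
            # concentration rows
            for k in range(2):
                r = n + k * n + i
                A[r, r] += V / cfg.dt
                b[r] = V / cfg.dt * state.c[k][i]
                for j in (i - 1, i + 1):
                    if 0 <= j < n:
                        cf = 0.5 * (state.c[k][i] + state.c[k][j])
                        W = Td * z[k] / vt * cf
                        A[r, n + k * n + i] += Td
                        A[r, n + k * n + j] -= Td
                        A[r, i] += W
                        A[r, j] -= W
        x = np.linalg.solve(A, b)
        phi_oracle = x[:n]
        cK_oracle = x[n:2 * n]
        cCl_oracle = x[2 * n:]
        assert np.abs(new.phi - phi_oracle).max() < 1e-10
        assert np.abs(new.c[0] - cK_oracle).max() < 1e-10
        assert np.abs(new.c[1] - cCl_oracle).max() < 1e-10


class TestDebyePhysics:
    def test_charge_relaxation_rate(self):
        """A bulk charge perturbation decays with the analytic Debye
        relaxation time tau = eps_r eps0 vt / (F sum z^2 D c)."""
        g, mesh = small_box_2d(n=24, L=24.0)
        species = KCL
        cfg = SolverConfig(
            dt=5e-8,
            phi_dirichlet={"x-": 0.0},
        )
        state = init_state(species, [], mesh, electroneutral=False)
        # broad, small-amplitude K+ bump in the center
        X, Y = np.meshgrid(mesh.centers[0], mesh.centers[1], indexing="ij")
        bump = 0.5 * np.exp(-((X - 12) ** 2 + (Y - 12) ** 2) / (2 * 6.0**2))
        state.c[0] += bump.ravel()
        st = Stepper(mesh, species, [], [], cfg)
        center = mesh.ravel(12, 12, 0)
        rho = [charge_density(state)[center]]
        s = state
        for _ in range(8):
            s = st.step(s)
            rho.append(charge_density(s)[center])
        rho = np.array(rho)
        t = np.arange(len(rho)) * cfg.dt
        rate_fit = -np.polyfit(t, np.log(np.abs(rho)), 1)[0]
        vt = thermal_voltage(CONSTANTS)
        sigma = sum(
            sp.z**2 * sp.Di * 100.0 for sp in species
        )
        rate_analytic = CONSTANTS.F * sigma / (80.0 * CONSTANTS.eps0 * vt)
        assert rate_fit == pytest.approx(rate_analytic, rel=0.2)

    def test_refinement_changes_decay_time_by_under_5_percent(self):
        """Halving both the time step and the mesh spacing moves the
        electroneutrality-decay time by < 5% (scheme convergence)."""

        def decay_time(h, dt):
            g = DomainGeometry(Le=0.0, Lm=0.0, Li=30.0, Ly=30.0, Lz=1.0, dims=2)
            mesh = build_mesh(g, [], fine_dx=h, fine_dyz=h, uniform=True)
            cfg = SolverConfig(
                dt=dt,
                phi_dirichlet={s: 0.0 for s in ("x-", "x+", "y-", "y+")},
                conc_dirichlet={s: {"K": 100.0, "Cl": 100.0}
                                for s in ("x-", "x+", "y-", "y+")},
            )
            state = init_state(KCL, [], mesh, electroneutral=False)
            X, Y = np.meshgrid(mesh.centers[0], mesh.centers[1], indexing="ij")
            state.c[0] += (10.0 * np.exp(
                -((X - 15) ** 2 + (Y - 15) ** 2) / (2 * 4.0**2))).ravel()
            st = Stepper(mesh, KCL, [], [], cfg)
            center = mesh.ravel(mesh.shape[0] // 2, mesh.shape[1] // 2, 0)
            rho0 = charge_density(state)[center]
            times, fracs = [0.0], [1.0]
            s = state
            for i in range(int(round(3e-6 / dt))):
                s = st.step(s)
                times.append(s.t)
                fracs.append(abs(charge_density(s)[center] / rho0))
            fracs = np.array(fracs)
            i = int(np.argmax(fracs < 0.05))
            return float(np.interp(
                0.05, fracs[i - 1:i + 1][::-1], np.array(times[i - 1:i + 1])[::-1]
            ))

        coarse = decay_time(1.0, 5e-8)
        fine = decay_time(0.5, 2.5e-8)
        assert abs(fine - coarse) <= 0.05 * coarse

    def test_negative_concentration_guard(self):
        g, mesh = small_box_2d(n=8, L=8.0)
        species = KCL
        state = init_state(species, [], mesh, electroneutral=False)
        state.c[0][:] = 1e-12  # vanishing K+: strong drift undershoots
        state.c[0][0] = 1.0
        state.rho0[:] = 0.0
        cfg = SolverConfig(dt=1e-4, phi_dirichlet={"x-": 0.0})
        st = Stepper(mesh, species, [], [], cfg)
        try:
            out = st.step(state)
            assert out.c.min() >= -cfg.neg_conc_tol
        except SolverError as err:
            assert "negative concentration" in str(err)
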