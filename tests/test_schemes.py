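"""Field-evolution schemes: fixed points, conservation, oracles,
cross-scheme equivalences and the Newton solver contract."""

import numpy as np
import pytest
import scipy.sparse as sp

import electrodiff as ed
from electrodiff import (
    BoundarySpec,
    NewtonOptions,
    SchemeConfig,
    apply_zero_mean,
    electroneutrality_drift,
    initial_state,
    newton_solve,
    solve_diff_potential,
    solve_vc_potential,
)
from electrodiff.applications import (
    analytic_step_diffusion,
    binary_ion_set,
    vc_point_source_potential,
)
from electrodiff.grid import assemble_div_a_grad, build_grid, probe, total_content
from electrodiff.schemes import (
    DOScheme,
    KNPScheme,
    NewtonError,
    PNPScheme,
    VCScheme,
    _solve_pinned,
)
from electrodiff.sources import CompartmentSource, SourceSet


def nax_step_state(n=201, extent=50e-6, c_lo=140.0, c_hi=150.0):
    ions = binary_ion_set()
    grid = build_grid(1, (-extent, extent), 2 * extent / (n - 1))
    x = grid.axes[0]
    c0 = np.where(x <= 0, c_lo, c_hi)
    return initial_state(grid, ions, np.stack([c0, c0]))


def balanced_pair(grid, I=0.1e-9, species="K"):
    lo = np.array([e[0] for e in grid.extents])
    hi = np.array([e[1] for e in grid.extents])
    a = lo + 0.3 * (hi - lo)
    b = lo + 0.7 * (hi - lo)
    comps = [
        CompartmentSource(0, a, {species: np.full(1, I)}),
        CompartmentSource(1, b, {species: np.full(1, -I)}),
    ]
    return SourceSet(comps, t0=0.0, dt_source=10.0)


class TestNewtonSolver:
    def test_linear_problem_single_iteration(self):
        A = sp.csr_matrix(np.array([[2.0, 1.0], [0.0, 3.0]]))
        b = np.array([1.0, 2.0])
        u, iters, _ = newton_solve(lambda u: A @ u - b, lambda u: A,
                                   np.zeros(2))
        np.testing.assert_allclose(A @ u, b, atol=1e-12)
        assert iters == 1

    def test_scalar_quadratic(self):
        resid = lambda u: np.array([u[0] ** 2 - 4.0])
        jac = lambda u: sp.csr_matrix([[2.0 * u[0]]])
        u, iters, _ = newton_solve(resid, jac, np.array([3.0]),
                                   NewtonOptions(rel_tol=1e-15))
        assert u[0] == pytest.approx(2.0, abs=1e-9)
        assert iters <= 12  # near-quadratic with factorisation reuse

    def test_max_iter_raises(self):
        resid = lambda u: np.array([np.exp(u[0]) + 1.0])  # no root
        jac = lambda u: sp.csr_matrix([[np.exp(u[0])]])
        with pytest.raises(NewtonError):
            newton_solve(resid, jac, np.array([0.0]),
                         NewtonOptions(max_iter=5))

    def test_knp_iteration_count_deterministic(self):
        counts = []
        for _ in range(2):
            state = nax_step_state(n=101)
            sch = KNPScheme(state.grid, state.ions, BoundarySpec("sealed"),
                            SchemeConfig(scheme="KNP", dt=1e-3))
            _, rep = sch.step(state)
            counts.append(rep.newton_iters)
        assert counts[0] == counts[1]
        assert 1 <= counts[0] <= 6


class TestZeroMean:
    def test_constant_field_maps_to_zero(self):
        g = build_grid(1, (0, 1), 0.1)
        out = apply_zero_mean(np.full(g.n_nodes, 3.7), g)
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_idempotent(self, rng):
        g = build_grid(1, (0, 1), 0.1)
        v = apply_zero_mean(rng.normal(size=g.n_nodes), g)
        np.testing.assert_allclose(apply_zero_mean(v, g), v, atol=1e-14)

    def test_output_mean_zero(self, rng):
        g = build_grid(3, [(0, 1)] * 3, 0.25)
        v = apply_zero_mean(rng.normal(size=g.n_nodes), g)
        w = g.node_volumes()
        assert abs(np.dot(w, v) / w.sum()) < 1e-14


class TestDiffusionOnly:
    def test_uniform_state_is_fixed_point(self, ecs_ions):
        grid = build_grid(1, (0, 10e-6), 0.5e-6)
        state = initial_state(grid, ecs_ions)
        sch = DOScheme(grid, ecs_ions, BoundarySpec("sealed"))
        new, _ = sch.step(state, dt=1e-3)
        np.testing.assert_allclose(new.c, state.c, rtol=1e-13)

    def test_step_profile_matches_erf_oracle(self):
        # free-space closed form, interior, before boundary influence
        state = nax_step_state(n=501)
        sch = DOScheme(state.grid, state.ions, BoundarySpec("sealed"),
                       SchemeConfig(scheme="DO", dt=2e-3))
        for _ in range(100):
            state, _ = sch.step(state)
        x = state.grid.axes[0]
        interior = np.abs(x) < 25e-6
        for k in range(2):
            oracle = analytic_step_diffusion(x, state.t, state.ions.D_eff[k],
                                             140.0, 150.0)
            rel = np.abs(state.c[k] - oracle) / oracle
            assert rel[interior].max() < 5e-3

    def test_sealed_mass_conservation(self):
        state = nax_step_state(n=201)
        total0 = [total_content(state.c[k], state.grid) for k in range(2)]
        sch = DOScheme(state.grid, state.ions, BoundarySpec("sealed"),
                       SchemeConfig(scheme="DO", dt=10e-3))
        for _ in range(50):
            state, _ = sch.step(state)
        for k in range(2):
            total = total_content(state.c[k], state.grid)
            assert abs(total - total0[k]) / total0[k] < 1e-10

    def test_violates_electroneutrality_constraint(self):
        # independent diffusion separates unequal-mobility ions by design
        state = nax_step_state(n=201)
        sch = DOScheme(state.grid, state.ions, BoundarySpec("sealed"),
                       SchemeConfig(scheme="DO", dt=10e-3))
        new, rep = sch.step(state)
        assert rep.charge_drift > 1.0  # C/(m^3 s): grossly nonzero


class TestVCPotential:
    def test_no_sources_zero_potential(self, ecs_ions):
        grid = build_grid(3, [(0, 100e-6)] * 3, 10e-6)
        state = initial_state(grid, ecs_ions)
        phi = solve_vc_potential(state, None)
        np.testing.assert_allclose(phi, 0.0, atol=1e-15)

    def test_point_source_matches_free_space_green_function(self, ecs_ions):
        # grounded large box, single source far from walls; the system is
        # driven by a companion sink placed near the boundary corner
        grid = build_grid(3, [(0, 200e-6)] * 3, 5e-6)
        state = initial_state(grid, ecs_ions)
        sigma = ed.conductivity(ecs_ions.c_baseline, ecs_ions)
        src = (100e-6, 100e-6, 100e-6)
        comps = [CompartmentSource(0, np.array(src), {"K": np.full(1, 0.1e-9)})]
        with pytest.warns(UserWarning):
            ss = SourceSet(comps, t0=0.0, dt_source=10.0)
        phi = solve_vc_potential(state, ss, boundary=BoundarySpec(
            kind="clamp", potential_bc="grounded"), dt=1.0)
        got = probe(phi, (100e-6, 105e-6, 100e-6), grid)
        want = vc_point_source_potential((100e-6, 105e-6, 100e-6),
                                         [(src, 0.1e-9)], sigma, 0.2)
        assert want == pytest.approx(10.4e-6, rel=0.02)  # the textbook value
        assert got == pytest.approx(want, rel=0.12)  # lattice + wall effects

    def test_source_sink_antisymmetry(self, ecs_ions):
        grid = build_grid(3, [(0, 100e-6), (0, 100e-6), (0, 40e-6)], 5e-6)
        state = initial_state(grid, ecs_ions)
        ss = balanced_pair(grid, I=0.1e-9)
        phi = solve_vc_potential(state, ss, dt=1.0)
        mid = probe(phi, (50e-6, 50e-6, 20e-6), grid)
        assert abs(mid) < 1e-12
        a = probe(phi, (30e-6, 30e-6, 20e-6), grid)
        b = probe(phi, (70e-6, 70e-6, 20e-6), grid)
        assert a == pytest.approx(-b, rel=1e-9)

    def test_unbalanced_source_with_neumann_boundary_reported(self, ecs_ions):
        grid = build_grid(3, [(0, 100e-6)] * 3, 10e-6)
        state = initial_state(grid, ecs_ions)
        comps = [CompartmentSource(0, np.full(3, 50e-6), {"K": np.full(1, 1e-9)})]
        with pytest.warns(UserWarning):
            ss = SourceSet(comps, t0=0.0, dt_source=10.0)
        with pytest.raises(ValueError, match="balance"):
            solve_vc_potential(state, ss, dt=1.0)


class TestDiffPotential:
    def test_uniform_concentrations_zero(self, ecs_ions):
        grid = build_grid(1, (0, 100e-6), 1e-6)
        state = initial_state(grid, ecs_ions)
        phi = solve_diff_potential(state)
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_binary_gradient_matches_junction_formula(self):
        ions = binary_ion_set()
        grid = build_grid(1, (0, 100e-6), 0.5e-6)
        x = grid.axes[0] / 100e-6
        c = 140 + 10 * (3 * x**2 - 2 * x**3)  # smooth 140 -> 150
        state = initial_state(grid, ions, np.stack([c, c]))
        phi = solve_diff_potential(state)
        dphi = phi[-1] - phi[0]
        want = ed.junction_potential_binary(140, 150, *ions.D_eff,
                                            ions.constants.psi)
        assert dphi == pytest.approx(want, rel=1e-2)

    def test_decomposition_matches_single_field_equation(self, ecs_ions, rng):
        # phi_VC + phi_diff must solve the combined elliptic equation
        grid = build_grid(3, [(0, 100e-6), (0, 100e-6), (0, 40e-6)], 10e-6)
        c = np.repeat(ecs_ions.c_baseline[:, None], grid.n_nodes, axis=1)
        c += rng.uniform(0, 0.5, size=c.shape)  # mild random gradients
        state = initial_state(grid, ecs_ions, c)
        ss = balanced_pair(grid, I=0.05e-9)
        from electrodiff.sources import deposit

        f_hat, i_cap = deposit(ss, grid, 0.0, 1.0, ecs_ions)
        phi_vc = solve_vc_potential(state, (f_hat, i_cap))
        phi_diff = solve_diff_potential(state)
        # direct single-field assembly
        sigma = ed.conductivity(state.c, ecs_ions)
        b = ed.diffusive_potential_coefficient_b(state.c, ecs_ions)
        F = ecs_ions.constants.F
        src = F * np.tensordot(ecs_ions.z, f_hat, axes=(0, 0)) + i_cap
        L1 = assemble_div_a_grad(grid, np.ones(grid.n_nodes))
        A = assemble_div_a_grad(grid, sigma)
        phi_direct = _solve_pinned(A, -(src + L1 @ b), grid, BoundarySpec(),
                                   zero_mean=True)
        np.testing.assert_allclose(phi_vc + phi_diff, phi_direct, atol=5e-11)


class TestKNP:
    def test_uniform_state_fixed_point_one_iteration(self, ecs_ions):
        grid = build_grid(1, (0, 10e-6), 0.5e-6)
        state = initial_state(grid, ecs_ions)
        sch = KNPScheme(grid, ecs_ions, BoundarySpec("sealed"))
        new, rep = sch.step(state, dt=1e-3)
        np.testing.assert_allclose(new.c, state.c, rtol=1e-12)
        np.testing.assert_allclose(new.phi, 0.0, atol=1e-12)
        assert rep.newton_iters <= 1

    def test_binary_profile_matches_ambipolar_erf_oracle(self):
        # coupled NaX moves as one species with the harmonic-mean coefficient
        state = nax_step_state(n=501)
        D_nax = ed.binary_salt_diffusion(*state.ions.D_eff)
        assert D_nax == pytest.approx(0.62779e-9, rel=1e-4)
        sch = KNPScheme(state.grid, state.ions, BoundarySpec("sealed"),
                        SchemeConfig(scheme="KNP", dt=5e-3))
        for _ in range(200):
            state, _ = sch.step(state)
        x = state.grid.axes[0]
        interior = np.abs(x) < 25e-6
        oracle = analytic_step_diffusion(x, state.t, D_nax, 140.0, 150.0)
        for k in range(2):
            rel = np.abs(state.c[k] - oracle) / oracle
            assert rel[interior].max() < 1e-2
        # anion and cation coincide
        assert np.abs(state.c[0] - state.c[1]).max() < 1e-2

    def test_quasi_steady_junction_potential(self):
        state = nax_step_state(n=2001, extent=0.1e-6)
        sch = KNPScheme(state.grid, state.ions, BoundarySpec("sealed"),
                        SchemeConfig(scheme="KNP", dt=0.1e-9))
        state, _ = sch.step(state)
        dphi = state.phi[-1] - state.phi[0]
        want = ed.junction_potential_binary(140, 150, *state.ions.D_eff,
                                            state.ions.constants.psi)
        assert dphi == pytest.approx(want, rel=2e-2)

    def test_sealed_mass_conservation(self):
        state = nax_step_state(n=201)
        total0 = [total_content(state.c[k], state.grid) for k in range(2)]
        sch = KNPScheme(state.grid, state.ions, BoundarySpec("sealed"),
                        SchemeConfig(scheme="KNP", dt=10e-3))
        for _ in range(20):
            state, _ = sch.step(state)
        for k in range(2):
            total = total_content(state.c[k], state.grid)
            assert abs(total - total0[k]) / total0[k] < 1e-9

    def test_electroneutrality_drift_below_newton_tolerance(self):
        state = nax_step_state(n=201)
        sch = KNPScheme(state.grid, state.ions, BoundarySpec("sealed"),
                        SchemeConfig(scheme="KNP", dt=1e-3))
        new, rep = sch.step(state)
        assert rep.charge_drift <= sch.drift_tolerance(1e-3)

    def test_clamp_boundary_passes_no_net_charge(self, ecs_ions):
        # with clamped concentrations, the boundary rows stay at the
        # electroneutral baseline, so total charge in the box is conserved
        grid = build_grid(3, [(0, 60e-6), (0, 60e-6), (0, 30e-6)], 10e-6)
        state = initial_state(grid, ecs_ions)
        ss = balanced_pair(grid, I=0.05e-9)
        sch = KNPScheme(grid, ecs_ions, BoundarySpec("clamp"),
                        SchemeConfig(scheme="KNP", dt=2e-3))
        rho0 = total_content(ed.charge_density(state.c, ecs_ions), grid)
        for _ in range(5):
            state, rep = sch.step(state, ss)
        rho = total_content(ed.charge_density(state.c, ecs_ions), grid)
        scale = ecs_ions.constants.F * total_content(
            np.abs(state.c).sum(axis=0), grid)
        assert abs(rho - rho0) / scale < 1e-12

    def test_diffusive_terms_disabled_recovers_vc(self, ecs_ions):
        grid = build_grid(3, [(0, 60e-6), (0, 60e-6), (0, 30e-6)], 10e-6)
        ss = balanced_pair(grid, I=0.05e-9)
        state = initial_state(grid, ecs_ions)
        cfg = SchemeConfig(scheme="KNP", dt=2e-3, knp_disable_diffusive=True,
                           knp_freeze_concentrations=True)
        knp = KNPScheme(grid, ecs_ions, BoundarySpec("clamp"), cfg)
        new, _ = knp.step(state, ss)
        vc = VCScheme(grid, ecs_ions, BoundarySpec("clamp"),
                      SchemeConfig(scheme="VC", dt=2e-3))
        vc_state, _ = vc.step(state, ss)
        np.testing.assert_allclose(new.phi_vc, vc_state.phi_vc, atol=1e-12)
        np.testing.assert_allclose(new.phi_diff, 0.0, atol=1e-12)
        np.testing.assert_allclose(new.c, state.c)

    def test_migration_disabled_recovers_do(self):
        # dropping the drift term reduces the species update to pure diffusion
        state = nax_step_state(n=101)
        cfg = SchemeConfig(scheme="KNP", dt=5e-3, knp_disable_migration=True)
        knp = KNPScheme(state.grid, state.ions, BoundarySpec("sealed"), cfg)
        knp_state, _ = knp.step(state)
        do = DOScheme(state.grid, state.ions, BoundarySpec("sealed"),
                      SchemeConfig(scheme="DO", dt=5e-3))
        do_state, _ = do.step(state)
        np.testing.assert_allclose(knp_state.c, do_state.c, rtol=1e-9)


class TestPNP:
    def test_uniform_electroneutral_fixed_point(self, ecs_ions):
        grid = build_grid(1, (0, 20e-9), 1e-9)
        state = initial_state(grid, ecs_ions)
        sch = PNPScheme(grid, ecs_ions, BoundarySpec("sealed"))
        new, rep = sch.step(state, dt=0.1e-9)
        np.testing.assert_allclose(new.c, state.c, rtol=1e-12)
        assert rep.newton_iters <= 1

    def test_coarse_grid_warns(self, ecs_ions):
        grid = build_grid(1, (0, 10e-6), 1e-6)
        with pytest.warns(UserWarning, match="Debye"):
            PNPScheme(grid, ecs_ions, BoundarySpec("sealed"))

    def test_relaxes_to_quasi_steady_with_debye_time(self):
        # potential difference approaches the junction value with an
        # e-folding time eps/sigma (~1 ns)
        state = nax_step_state(n=101, extent=0.02e-6)
        ions = state.ions
        sigma = ed.conductivity([145.0, 145.0], ions)
        tau = ions.constants.eps / sigma
        sch = PNPScheme(state.grid, ions, BoundarySpec("sealed"),
                        SchemeConfig(scheme="PNP", dt=0.05e-9))
        dphis, times = [], []
        for _ in range(400):
            state, _ = sch.step(state)
            dphis.append(state.phi[-1] - state.phi[0])
            times.append(state.t)
        dphis, times = np.array(dphis), np.array(times)
        target = dphis[-1]
        # fit log-linear decay of the gap over the first few ns
        gap = np.abs(target - dphis) / abs(target)
        mask = (gap > 1e-3) & (times < 5e-9)
        rate = np.polyfit(times[mask], np.log(gap[mask]), 1)[0]
        assert -1.0 / rate == pytest.approx(tau, rel=0.35)

    def test_sealed_mass_conservation(self):
        state = nax_step_state(n=101, extent=0.02e-6)
        total0 = [total_content(state.c[k], state.grid) for k in range(2)]
        sch = PNPScheme(state.grid, state.ions, BoundarySpec("sealed"),
                        SchemeConfig(scheme="PNP", dt=0.1e-9))
        for _ in range(50):
            state, _ = sch.step(state)
        for k in range(2):
            total = total_content(state.c[k], state.grid)
            assert abs(total - total0[k]) / total0[k] < 1e-9


class TestVCScheme:
    def test_concentrations_frozen(self, ecs_ions):
        grid = build_grid(3, [(0, 60e-6), (0, 60e-6), (0, 30e-6)], 10e-6)
        state = initial_state(grid, ecs_ions)
        ss = balanced_pair(grid)
        sch = VCScheme(grid, ecs_ions, BoundarySpec("clamp"),
                       SchemeConfig(scheme="VC", dt=2e-3))
        new, _ = sch.step(state, ss)
        np.testing.assert_array_equal(new.c, state.c)
        assert np.abs(new.phi).max() > 0

    def test_constant_sigma_mode_matches_at_baseline(self, ecs_ions):
        grid = build_grid(3, [(0, 60e-6), (0, 60e-6), (0, 30e-6)], 10e-6)
        state = initial_state(grid, ecs_ions)
        ss = balanced_pair(grid)
        a = VCScheme(grid, ecs_ions, BoundarySpec("clamp"),
                     SchemeConfig(scheme="VC", dt=2e-3)).step(state, ss)[0]
        b = VCScheme(grid, ecs_ions, BoundarySpec("clamp"),
                     SchemeConfig(scheme="VC", dt=2e-3,
                                  vc_constant_sigma=True)).step(state, ss)[0]
        np.testing.assert_allclose(a.phi, b.phi, atol=1e-12)
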