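"""Method-of-lines simulator against the analytic oracles."""

import numpy as np
import pytest

import fibrostab as fs
from fibrostab.simulate import discrete_mode_eigenvalue, laplacian_matrix


@pytest.fixture(scope="module")
def grid():
    return fs.Grid.interval(np.pi, 101)


def mode_init(grid, amplitudes, n=1):
    phi = np.cos(n * np.pi * grid.axes[0] / grid.extents[0])
    return np.asarray(amplitudes)[:, None] * phi[None, :]


class TestGridAndModes:
    def test_grid_contract(self):
        g = fs.Grid.interval(2.0, 21)
        assert g.ndim == 1 and g.spacing == (0.1,)
        with pytest.raises(ValueError):
            fs.Grid.interval(1.0, 4)

    def test_neumann_modes_interval(self, grid):
        modes = fs.neumann_laplacian_modes(grid, 3)
        mu0, phi0 = modes[0]
        assert mu0 == 0.0 and np.allclose(phi0, 1.0)
        mu1, phi1 = modes[1]
        assert mu1 == pytest.approx(1.0)  # (pi/L)^2 with L = pi
        np.testing.assert_allclose(phi1, np.cos(grid.axes[0]))

    def test_mode_count_validation(self, grid):
        with pytest.raises(ValueError):
            fs.neumann_laplacian_modes(grid, 0)
        with pytest.raises(ValueError):
            fs.neumann_laplacian_modes(grid, 500)

    def test_rectangle_modes_are_tensor_products(self):
        g = fs.Grid.rectangle((np.pi, 2 * np.pi), (16, 24))
        modes = fs.neumann_laplacian_modes(g, 4)
        mus = [m for m, _ in modes]
        assert mus == sorted(mus)
        assert mus[0] == 0.0
        assert mus[1] == pytest.approx(0.25)  # first mode along the long axis

    def test_cosine_modes_are_exact_discrete_eigenvectors(self, grid):
        L = laplacian_matrix(grid)
        for n in (1, 2, 5):
            phi = np.cos(n * grid.axes[0])
            mu_h = discrete_mode_eigenvalue(grid, n)
            np.testing.assert_allclose(L @ phi, -mu_h * phi, atol=1e-10)

    def test_discrete_eigenvalue_second_order_convergence(self):
        exact = 4.0  # n = 2 on [0, pi]
        errs = []
        for npts in (26, 51, 101):
            g = fs.Grid.interval(np.pi, npts)
            errs.append(abs(discrete_mode_eigenvalue(g, 2) - exact))
        assert errs[1] / errs[0] == pytest.approx(0.25, rel=0.1)
        assert errs[2] / errs[1] == pytest.approx(0.25, rel=0.1)


class TestSimulateLinearized:
    def test_zero_init_stays_zero(self, grid, stable_params):
        c = fs.linear_coefficients(stable_params, fs.interior_equilibrium(stable_params))
        sol = fs.simulate_linearized(c, stable_params, np.zeros((5, 101)), grid, 1.0)
        assert np.all(sol.fields == 0.0) and np.all(sol.l2_norms == 0.0)

    def test_single_mode_follows_modal_eigenvalue(self, grid):
        """Init on a modal eigenvector of the discrete mode: the decay rate
        must match that eigenvalue to integrator accuracy."""
        s = fs.counterexample_params(1.0, 1.0, "stable")
        mu_h = discrete_mode_eigenvalue(grid, 1)
        w, V = np.linalg.eig(-fs.modal_matrix(s.coeffs, s.diffusivities, mu_h))
        i = np.argmax(w.real)
        assert abs(w[i].imag) < 1e-12  # dominant root of the quadratic is real here
        sol = fs.simulate_linearized(
            s.coeffs, s.diffusivities, mode_init(grid, V[:, i].real), grid, 2.0
        )
        fit = fs.growth_rate_estimate(sol)
        assert fit.rate == pytest.approx(w[i].real, rel=1e-4)
        assert fit.r_squared > 0.999999

    def test_mode_rate_matches_continuous_mu_within_5pc(self, grid):
        s = fs.counterexample_params(1.0, 1.0, "stable")
        mu_h = discrete_mode_eigenvalue(grid, 1)
        w, V = np.linalg.eig(-fs.modal_matrix(s.coeffs, s.diffusivities, mu_h))
        i = np.argmax(w.real)
        sol = fs.simulate_linearized(
            s.coeffs, s.diffusivities, mode_init(grid, V[:, i].real), grid, 2.0
        )
        sig_cont, _ = fs.modal_eigenvalues(s.coeffs, s.diffusivities, 1.0)
        rate = fs.growth_rate_estimate(sol).rate
        assert rate == pytest.approx(sig_cont.real.max(), rel=0.05)

    def test_modal_rate_error_shrinks_second_order(self):
        s = fs.counterexample_params(1.0, 1.0, "stable")
        sig_cont, _ = fs.modal_eigenvalues(s.coeffs, s.diffusivities, 1.0)
        target = sig_cont.real.max()
        errs = []
        for npts in (26, 101):
            g = fs.Grid.interval(np.pi, npts)
            mu_h = discrete_mode_eigenvalue(g, 1)
            w, V = np.linalg.eig(-fs.modal_matrix(s.coeffs, s.diffusivities, mu_h))
            i = np.argmax(w.real)
            sol = fs.simulate_linearized(
                s.coeffs, s.diffusivities, mode_init(g, V[:, i].real, n=1), g, 1.0,
                rtol=1e-10, atol=1e-12,
            )
            errs.append(abs(fs.growth_rate_estimate(sol).rate - target))
        # 4x finer grid -> ~16x smaller discretization error
        assert errs[1] < 0.12 * errs[0]

    def test_counterexample_unstable_mode_grows_to_cap(self, grid):
        s = fs.counterexample_params(1.0, 1.0, "unstable")
        sol = fs.simulate_linearized(
            s.coeffs, s.diffusivities, mode_init(grid, np.ones(5)), grid, 400.0,
            blowup_cap=1e6,
        )
        assert sol.blowup
        assert sol.l2_norms[-1] > 1e4 * sol.l2_norms[0]

    def test_zero_mean_is_conserved(self, grid, stable_params):
        c = fs.linear_coefficients(stable_params, fs.interior_equilibrium(stable_params))
        rng = np.random.default_rng(5)
        init = rng.standard_normal((5, 101))
        w = grid.quad_weights()
        init -= (init * w).sum(axis=1, keepdims=True) / w.sum()  # zero-mean data
        sol = fs.simulate_linearized(c, stable_params, init, grid, 2.0)
        scale = np.abs(sol.fields).max()
        assert np.abs(sol.means).max() < 1e-8 * scale


class TestSimulateFull:
    def test_uniform_equilibrium_is_stationary(self, stable_params):
        g = fs.Grid.interval(np.pi, 33)
        eq = fs.interior_equilibrium(stable_params).as_array()
        init = eq[:, None] * np.ones((5, 33))
        sol = fs.simulate_full(stable_params, init, g, 10.0, reference=init)
        assert sol.l2_norms.max() < 1e-6

    def test_uniform_data_reproduces_reaction_ode(self, stable_params):
        g = fs.Grid.interval(np.pi, 33)
        s0 = np.array([0.3, 0.4, 2.0, 0.8, 0.5])
        sol = fs.simulate_full(stable_params, s0[:, None] * np.ones((5, 33)), g, 5.0)
        traj = fs.integrate_reactions(s0, stable_params, 5.0, n_out=sol.times.size)
        mid = sol.fields[:, :, 16]
        np.testing.assert_allclose(mid, traj.states, rtol=1e-5, atol=1e-7)

    def test_small_perturbation_decays_for_ode_stable_params(self, stable_params):
        g = fs.Grid.interval(np.pi, 41)
        eq = fs.interior_equilibrium(stable_params).as_array()
        base = eq[:, None] * np.ones((5, 41))
        rng = np.random.default_rng(2)
        init = np.clip(base * (1 + 1e-3 * rng.standard_normal((5, 41))), 0.0, None)
        sol = fs.simulate_full(stable_params, init, g, 40.0, reference=base)
        assert sol.l2_norms[-1] < 1e-2 * sol.l2_norms[0]

    def test_negative_init_rejected(self, stable_params):
        g = fs.Grid.interval(np.pi, 33)
        init = -np.ones((5, 33))
        with pytest.raises(ValueError, match="nonnegative"):
            fs.simulate_full(stable_params, init, g, 1.0)

    def test_2d_uniform_data_reproduces_ode(self, stable_params):
        g = fs.Grid.rectangle((1.0, 1.5), (9, 11))
        s0 = np.array([0.3, 0.4, 2.0, 0.8, 0.5])
        init = s0[:, None, None] * np.ones((5, 9, 11))
        sol = fs.simulate_full(stable_params, init, g, 2.0, n_out=21)
        traj = fs.integrate_reactions(s0, stable_params, 2.0, n_out=21)
        np.testing.assert_allclose(sol.fields[:, :, 4, 5], traj.states, rtol=1e-5, atol=1e-7)


class TestGrowthRateEstimate:
    def test_exact_exponential_recovered(self, grid):
        t = np.linspace(0.0, 4.0, 50)
        sol = fs.FieldSolution(
            grid=grid,
            times=t,
            fields=np.ones((50, 5, 101)),
            l2_norms=np.exp(-0.5 * t),
            means=np.zeros((50, 5)),
        )
        fit = fs.growth_rate_estimate(sol)
        assert fit.rate == pytest.approx(-0.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_norms_give_zero_rate(self, grid):
        t = np.linspace(0.0, 4.0, 20)
        sol = fs.FieldSolution(
            grid=grid, times=t, fields=np.ones((20, 5, 101)),
            l2_norms=np.ones(20), means=np.zeros((20, 5)),
        )
        assert fs.growth_rate_estimate(sol).rate == pytest.approx(0.0, abs=1e-14)

    def test_nonpositive_norms_rejected(self, grid):
        t = np.linspace(0.0, 4.0, 20)
        sol = fs.FieldSolution(
            grid=grid, times=t, fields=np.ones((20, 5, 101)),
            l2_norms=np.zeros(20), means=np.zeros((20, 5)),
        )
        with pytest.raises(ValueError, match="positive"):
            fs.growth_rate_estimate(sol)
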