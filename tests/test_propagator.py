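import numpy as np
import pytest

from affectdiffusion import (
    AIMParameters,
    ProbabilityField,
    build_grid,
    build_kernel,
    delta_field,
    mh_step,
    propagate,
    stationary_field,
    tabulate_potential,
)
from affectdiffusion.optimize import sample_prior
from affectdiffusion.potentials import PotentialSurface


def make_surface(values_interior, params=None):
    """Assemble a surface directly from an interior matrix (ghosts infinite)."""
    n = values_interior.shape[0]
    grid = build_grid(n)
    values = np.full((n + 2, n + 2), np.inf)
    values[1:-1, 1:-1] = values_interior
    return PotentialSurface(grid=grid, values=values, params=params or AIMParameters(D=1))


def random_surface(rng, n=30):
    return make_surface(rng.uniform(0, 3, size=(n, n)))


class TestBuildKernel:
    def test_flat_surface_unit_acceptance(self, grid30, flat_params):
        k = build_kernel(tabulate_potential(flat_params, grid30), flat_params.D)
        # interior-neighbor moves are always accepted on a flat surface
        assert np.all(k.accept[0, 1:, :] == 1.0)
        assert np.all(k.accept[1, :-1, :] == 1.0)
        assert np.all(k.accept[2, :, 1:] == 1.0)
        assert np.all(k.accept[3, :, :-1] == 1.0)

    def test_ghost_directions_zero(self, bimodal_params, grid30):
        k = build_kernel(tabulate_potential(bimodal_params, grid30), bimodal_params.D)
        assert np.all(k.accept[0, 0, :] == 0.0)  # top row cannot move up
        assert np.all(k.accept[1, -1, :] == 0.0)
        assert np.all(k.accept[2, :, 0] == 0.0)
        assert np.all(k.accept[3, :, -1] == 0.0)

    def test_uphill_acceptance_value(self):
        interior = np.full((4, 4), 0.5)
        interior[0, :] = 1.0  # moving from row 1 up to row 0 costs dF = 0.5
        k = build_kernel(make_surface(interior), D=1.0)
        assert k.accept[0, 1, 0] == pytest.approx(np.exp(-0.5))  # 0.606531
        assert k.accept[1, 0, 0] == 1.0  # downhill always accepted

    def test_step_size_law(self, grid30, flat_params):
        k = build_kernel(tabulate_potential(flat_params, grid30), D=1.0)
        assert k.dt == (1 / 30) ** 2 / 5.0  # 1/4500 ≈ 2.2222e-4 h
        assert k.dt == pytest.approx(2.2222e-4, rel=1e-4)

    def test_nonpositive_d_rejected(self, grid30, flat_params):
        surf = tabulate_potential(flat_params, grid30)
        with pytest.raises(ValueError):
            build_kernel(surf, 0.0)


class TestMHStep:
    def test_flat_delta_spreads_one_fifth(self, grid30, flat_params):
        k = build_kernel(tabulate_potential(flat_params, grid30), flat_params.D)
        f = mh_step(delta_field(grid30, (0.5, 0.5)), k)
        assert f.masses[15, 15] == pytest.approx(0.2, abs=1e-15)
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            assert f.masses[15 + di, 15 + dj] == pytest.approx(0.2, abs=1e-15)
        assert f.steps == 1

    def test_corner_cell_keeps_three_fifths(self, grid30, flat_params):
        k = build_kernel(tabulate_potential(flat_params, grid30), flat_params.D)
        f = mh_step(delta_field(grid30, (0.0, 0.0)), k)
        assert f.masses[0, 0] == pytest.approx(0.6, abs=1e-15)
        assert f.masses[1, 0] == pytest.approx(0.2, abs=1e-15)
        assert f.masses[0, 1] == pytest.approx(0.2, abs=1e-15)

    def test_mass_conserved_on_random_surfaces(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            surf = random_surface(rng)
            k = build_kernel(surf, D=0.01)
            m = rng.random((30, 30))
            f = ProbabilityField(build_grid(30), m / m.sum())
            f2 = mh_step(f, k)
            assert abs(f2.total - f.total) <= 1e-15

    def test_nonnegativity_lower_bound(self):
        """Every cell retains at least a fifth of its mass each step."""
        rng = np.random.default_rng(4)
        surf = random_surface(rng)
        k = build_kernel(surf, D=0.01)
        m = rng.random((30, 30))
        f = ProbabilityField(build_grid(30), m / m.sum())
        f2 = mh_step(f, k)
        assert np.all(f2.masses >= f.masses / 5.0 - 1e-18)

    def test_boltzmann_field_invariant(self, bimodal_params, grid30):
        surf = tabulate_potential(bimodal_params, grid30)
        k = build_kernel(surf, bimodal_params.D)
        pi = stationary_field(surf)
        pi2 = mh_step(pi, k)
        np.testing.assert_allclose(pi2.masses, pi.masses, atol=1e-14)

    def test_detailed_balance(self, bimodal_params, grid30):
        """pi_i (1/5) k[i->j] equals pi_j (1/5) k[j->i] for every neighbor pair."""
        surf = tabulate_potential(bimodal_params, grid30)
        k = build_kernel(surf, bimodal_params.D)
        pi = stationary_field(surf).masses
        # down-neighbor pairs: (i, j) vs (i+1, j)
        lhs = pi[:-1, :] * k.accept[1, :-1, :] / 5.0
        rhs = pi[1:, :] * k.accept[0, 1:, :] / 5.0
        np.testing.assert_allclose(lhs, rhs, atol=1e-14)
        # right-neighbor pairs: (i, j) vs (i, j+1)
        lhs = pi[:, :-1] * k.accept[3, :, :-1] / 5.0
        rhs = pi[:, 1:] * k.accept[2, :, 1:] / 5.0
        np.testing.assert_allclose(lhs, rhs, atol=1e-14)

    def test_grid_mismatch_rejected(self, flat_params):
        k = build_kernel(tabulate_potential(flat_params, build_grid(30)), flat_params.D)
        with pytest.raises(ValueError):
            mh_step(delta_field(build_grid(15), (0.5, 0.5)), k)


class TestSelfTransition:
    def test_stay_probability_at_least_one_fifth(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            params = sample_prior(rng)
            k = build_kernel(tabulate_potential(params, build_grid(30)), params.D)
            assert k.stay_probability().min() >= 0.2 - 1e-15


class TestPropagate:
    def test_zero_duration_identity(self, grid30, flat_params):
        k = build_kernel(tabulate_potential(flat_params, grid30), flat_params.D)
        f = delta_field(grid30, (0.5, 0.5))
        out, steps = propagate(f, k, 0.0)
        assert steps == 0
        np.testing.assert_array_equal(out.masses, f.masses)

    @pytest.mark.parametrize("t", [1, 5, 50, 500])
    def test_commensurate_duration_exact_steps(self, bimodal_params, grid30, t):
        surf = tabulate_potential(bimodal_params, grid30)
        k = build_kernel(surf, bimodal_params.D)
        _, steps = propagate(delta_field(grid30, (0.3, 0.7)), k, t * k.dt)
        assert steps == t

    def test_short_positive_duration_floors_to_one_step(self, grid30, flat_params):
        k = build_kernel(tabulate_potential(flat_params, grid30), flat_params.D)
        _, steps = propagate(delta_field(grid30, (0.5, 0.5)), k, k.dt * 1e-3)
        assert steps == 1

    def test_negative_duration_rejected(self, grid30, flat_params):
        k = build_kernel(tabulate_potential(flat_params, grid30), flat_params.D)
        with pytest.raises(ValueError):
            propagate(delta_field(grid30, (0.5, 0.5)), k, -1.0)

    def test_long_run_converges_to_stationary(self):
        params = AIMParameters(lambda1=2, lambda2=1, lambda12=2, theta1=0.5,
                               theta2=1, n1=1, n2=1, D=0.01)
        grid = build_grid(30)
        surf = tabulate_potential(params, grid)
        k = build_kernel(surf, params.D)
        f, steps = propagate(delta_field(grid, (0.9, 0.1)), k, 1e5 * k.dt)
        assert steps == 100_000
        pi = stationary_field(surf)
        assert np.abs(f.masses - pi.masses).max() <= 1e-8


class TestStationaryField:
    def test_flat_surface_uniform(self, grid30, flat_params):
        pi = stationary_field(tabulate_potential(flat_params, grid30))
        np.testing.assert_allclose(pi.masses, 1 / 900, rtol=1e-14)

    def test_two_level_surface_boltzmann_ratio(self):
        interior = np.zeros((6, 6))
        interior[:3, :] = 1.0
        pi = stationary_field(make_surface(interior))
        assert pi.masses[5, 0] / pi.masses[0, 0] == pytest.approx(np.e, rel=1e-13)

    def test_degenerate_surface_rejected(self):
        surf = make_surface(np.full((4, 4), np.inf))
        with pytest.raises(ValueError):
            stationary_field(surf)


def test_flat_surface_displacement_variance_exact(grid30, flat_params):
    """With all acceptances 1 the per-step displacement variance is exactly 2 delta^2/5."""
    k = build_kernel(tabulate_potential(flat_params, grid30), flat_params.D)
    d2 = grid30.delta ** 2
    # interior cells (away from edges): both neighbors in each dimension accept
    var_dim1 = d2 * (k.accept[0] / 5.0 + k.accept[1] / 5.0)
    var_dim2 = d2 * (k.accept[2] / 5.0 + k.accept[3] / 5.0)
    assert np.all(var_dim1[1:-1, :] == 2 * d2 / 5)
    assert np.all(var_dim2[:, 1:-1] == 2 * d2 / 5)
    # and the law ties the step to D: <(dy)^2> = 2 D dt
    assert 2 * d2 / 5 == pytest.approx(2 * flat_params.D * k.dt, rel=1e-15)


def test_mass_conservation_many_steps():
    rng = np.random.default_rng(6)
    params = sample_prior(rng)
    grid = build_grid(30)
    k = build_kernel(tabulate_potential(params, grid), params.D)
    f = delta_field(grid, (0.42, 0.58))
    f, steps = propagate(f, k, 1000 * k.dt)
    assert steps == 1000
    assert abs(f.total - 1.0) <= 1e-12
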