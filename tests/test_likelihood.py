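import numpy as np
import pytest

from affectdiffusion import (
    AffectTimeSeries,
    AIMParameters,
    LikelihoodOptions,
    build_grid,
    delta_field,
    neg_log_likelihood,
    pair_neg_loglik,
    propagate,
)
from affectdiffusion.validation import rebin
from affectdiffusion.em import EMConfig, endpoints_to_field, simulate_endpoints
from affectdiffusion.esm import ScheduleConfig, esm_schedule, simulate_series
from affectdiffusion.grid import density_at
from affectdiffusion.likelihood import ModelContext, evaluated_pairs
from affectdiffusion.optimize import sample_prior


def series_from_points(points, gap=1.0, day=None):
    points = np.asarray(points, dtype=float)
    n = len(points)
    return AffectTimeSeries(
        t=np.arange(n) * gap,
        x=points,
        day=np.zeros(n, dtype=int) if day is None else np.asarray(day),
        valid=np.ones(n, dtype=bool),
    )


class TestPairNegLoglik:
    def test_flat_surface_long_interval_approaches_uniform(self):
        """Long propagation on a flat surface mixes to the uniform density (=1)."""
        params = AIMParameters(D=0.05)
        val = pair_neg_loglik(params, (0.2, 0.9), (0.7, 0.3), 40.0)
        assert abs(val) <= 1e-3

    def test_zero_mass_cell_hits_density_floor(self):
        """One step cannot reach a distant cell; the floor keeps -ln finite."""
        params = AIMParameters(D=0.01)
        k_dt = (1 / 30) ** 2 / (5 * params.D)
        val = pair_neg_loglik(params, (0.5, 0.5), (0.95, 0.05), k_dt)
        assert val == pytest.approx(-np.log(1e-300), rel=1e-12)  # about 690.8

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            pair_neg_loglik(AIMParameters(D=0.01), (0.5, 0.5), (0.5, 0.5), 0.0)

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_agrees_with_euler_maruyama_histogram(self, seed):
        """The lattice conditional density matches the trajectory-simulation oracle.

        Both solvers are binned to the 30-grid; the lattice runs at n=120 so
        its discretization error is small next to the Monte-Carlo error of
        1e5 trajectories.
        """
        rng = np.random.default_rng(seed)
        params = sample_prior(rng)
        x_from = rng.uniform(0.2, 0.8, 2)
        interval = 50 * (1 / 30) ** 2 / (5 * params.D)  # 50 default-grid steps
        ctx = ModelContext(params, 120)

        n_traj = 100_000
        ends = simulate_endpoints(
            params, x_from, interval,
            EMConfig(dt=(1 / 120) ** 2 / (5 * params.D), n_traj=n_traj), rng=rng,
        )
        em30 = endpoints_to_field(ends, build_grid(30))
        # probe a likely cell: the EM histogram mode
        i, j = np.unravel_index(np.argmax(em30.masses), em30.masses.shape)
        x_to = build_grid(30).cell_center(np.array([i, j]))

        mh120, _ = propagate(delta_field(ctx.grid, x_from), ctx.kernel, interval)
        mh30 = rebin(mh120, 30)
        p_hat = em30.masses[i, j]
        se = np.sqrt(p_hat * (1 - p_hat) / n_traj)
        assert abs(mh30.masses[i, j] - p_hat) <= 4 * se
        # the pairwise NLL agrees after converting the mass difference to log scale
        nll_mh = -np.log(mh30.masses[i, j] * 900.0)
        nll_em = -np.log(density_at(em30, x_to))
        assert abs(nll_mh - nll_em) <= 4 * se / p_hat


class TestNegLogLikelihood:
    def test_single_observation_skip_mode_is_zero(self):
        s = series_from_points([[0.5, 0.5]])
        val = neg_log_likelihood(AIMParameters(D=0.01), s,
                                 LikelihoodOptions(initial_mode="skip"))
        assert val == 0.0

    def test_flat_two_point_series_stationary_initial(self):
        """Uniform stationary density is 1, so both contributions vanish."""
        params = AIMParameters(D=0.05)
        s = series_from_points([[0.4, 0.4], [0.6, 0.7]], gap=40.0)
        val = neg_log_likelihood(params, s, LikelihoodOptions(initial_mode="stationary"))
        assert abs(val) <= 1e-3

    def test_night_pairs_skipped(self, bimodal_params):
        s_two_day = series_from_points(
            [[0.3, 0.3], [0.4, 0.4], [0.5, 0.5], [0.6, 0.6]],
            gap=1.0, day=[0, 0, 1, 1],
        )
        within = neg_log_likelihood(bimodal_params, s_two_day)
        day0 = neg_log_likelihood(bimodal_params, series_from_points([[0.3, 0.3], [0.4, 0.4]]))
        day1 = neg_log_likelihood(bimodal_params, series_from_points([[0.5, 0.5], [0.6, 0.6]]))
        assert within == pytest.approx(day0 + day1, rel=1e-12)

    def test_stationary_restart_adds_boltzmann_term(self, bimodal_params):
        s = series_from_points(
            [[0.3, 0.3], [0.4, 0.4], [0.5, 0.5]], gap=1.0, day=[0, 0, 1]
        )
        skip = neg_log_likelihood(bimodal_params, s)
        restart = neg_log_likelihood(
            bimodal_params, s, LikelihoodOptions(night_mode="stationary_restart")
        )
        ctx = ModelContext(bimodal_params, 30)
        expected_extra = ctx.stationary_nll((0.5, 0.5), 1e-300)
        assert restart - skip == pytest.approx(expected_extra, rel=1e-10)

    def test_missing_observations_bridged(self, bimodal_params):
        full = AffectTimeSeries(
            t=[0.0, 1.0, 2.5],
            x=[[0.3, 0.3], [np.nan, np.nan], [0.6, 0.6]],
            day=[0, 0, 0],
            valid=[True, False, True],
        )
        bridged = series_from_points([[0.3, 0.3], [0.6, 0.6]], gap=2.5)
        assert neg_log_likelihood(bimodal_params, full) == pytest.approx(
            neg_log_likelihood(bimodal_params, bridged), rel=1e-12
        )

    def test_caching_matches_uncached(self, bimodal_params):
        rng = np.random.default_rng(30)
        pts = rng.uniform(0.1, 0.9, size=(12, 2))
        s = series_from_points(pts, gap=1.3)
        a = neg_log_likelihood(bimodal_params, s, LikelihoodOptions(cache=True))
        b = neg_log_likelihood(bimodal_params, s, LikelihoodOptions(cache=False))
        assert a == pytest.approx(b, abs=1e-9)

    def test_step_cap_returns_sentinel(self):
        huge_d = AIMParameters(D=50.0)  # thousands of lattice steps per hour
        s = series_from_points([[0.4, 0.4], [0.6, 0.6]], gap=10.0)
        assert neg_log_likelihood(huge_d, s, LikelihoodOptions(step_cap=1000)) == np.inf

    def test_empty_series_rejected(self, bimodal_params):
        empty = AffectTimeSeries(t=[], x=np.empty((0, 2)), day=[], valid=[])
        with pytest.raises(ValueError):
            neg_log_likelihood(bimodal_params, empty)

    def test_finite_for_feasible_parameters(self):
        rng = np.random.default_rng(31)
        pts = rng.uniform(0.05, 0.95, size=(8, 2))
        s = series_from_points(pts, gap=1.1)
        for _ in range(5):
            params = sample_prior(rng)
            assert np.isfinite(neg_log_likelihood(params, s))


def test_true_parameters_beat_perturbed_diffusion(bimodal_params):
    """On simulated data the truth has smaller NLL than 2x or 0.5x D (majority vote)."""
    rng = np.random.default_rng(40)
    grid = build_grid(30)
    doubled = bimodal_params.replace(D=2 * bimodal_params.D)
    halved = bimodal_params.replace(D=0.5 * bimodal_params.D)
    wins_double = wins_half = 0
    n_series = 50
    for _ in range(n_series):
        sched = esm_schedule(ScheduleConfig(days=1, compliance=1.0), rng)
        s = simulate_series(bimodal_params, sched, grid, rng)
        ref = neg_log_likelihood(bimodal_params, s)
        wins_double += ref <= neg_log_likelihood(doubled, s)
        wins_half += ref <= neg_log_likelihood(halved, s)
    assert wins_double > n_series / 2
    assert wins_half > n_series / 2


def test_evaluated_pairs_structure():
    s = AffectTimeSeries(
        t=[0.0, 1.0, 2.0, 26.0, 27.0],
        x=[[0.1, 0.1], [0.2, 0.2], [np.nan, np.nan], [0.4, 0.4], [0.5, 0.5]],
        day=[0, 0, 0, 1, 1],
        valid=[True, True, False, True, True],
    )
    pairs, stat = evaluated_pairs(s, LikelihoodOptions(initial_mode="stationary"))
    assert stat == [(0.1, 0.1)]
    assert [(p.x_from, p.x_to, p.interval) for p in pairs] == [
        ((0.1, 0.1), (0.2, 0.2), 1.0),
        ((0.4, 0.4), (0.5, 0.5), 1.0),
    ]
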