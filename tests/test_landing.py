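import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import chisquare

from oculoread.landing import (
    GridSearchGaussian,
    LaunchSiteRegression,
    center_based_coordinates,
    fit_gaussian_gridsearch,
    fit_landing_function,
    forward_saccade_table,
    landing_cells,
    landing_histogram,
    landing_sd_profile,
    select_landing_letters,
    word_centers,
)
from oculoread.simulate import (
    SimulationConfig,
    sample_forward_saccades,
    simulate_experiment,
)
from oculoread.stats import classify_saccades


def discretized_counts(mu, sigma, length, n):
    """Counts from a Gaussian discretized and renormalized over a word."""
    edges = np.arange(0.5, length + 1.5)
    p = np.diff(ndtr((edges - mu) / sigma))
    p = p / p.sum()
    return np.round(p * n)


class TestCenterBasedCoordinates:
    def test_lands_on_center(self):
        assert center_based_coordinates(2.0, 6.0, 6.0) == (4.0, 0.0)

    def test_lands_left_of_center(self):
        assert center_based_coordinates(2.0, 5.0, 6.0) == (4.0, -1.0)

    def test_launch_right_of_center_rejected(self):
        with pytest.raises(ValueError):
            center_based_coordinates(7.0, 6.0, 6.0)


class TestLandingHistogram:
    def test_point_mass(self):
        np.testing.assert_allclose(
            landing_histogram([3, 3, 3], 5), [0, 0, 1, 0, 0]
        )

    def test_uniform(self):
        np.testing.assert_allclose(
            landing_histogram([1, 2, 3, 4], 4), [0.25] * 4
        )

    def test_empty_marker(self):
        assert np.isnan(landing_histogram([], 5)).all()


class TestGridSearchGaussian:
    def test_recovers_generating_parameters_within_one_grid_step(self):
        counts = discretized_counts(3.0, 1.2, 7, 10_000)
        fit = fit_gaussian_gridsearch(counts, 7)
        est = GridSearchGaussian()

        def objective(p):
            return est.chi2_surface(p[0], p[1], counts)

        bounds = [(0.5, 7.5), (0.3, 5.0)]  # same domain as the grid
        oracle = min(
            (
                minimize(objective, [m0, s0], method="Nelder-Mead", bounds=bounds)
                for m0 in (2.0, 4.0)
                for s0 in (0.8, 1.6)
            ),
            key=lambda r: r.fun,
        )
        assert abs(fit.mu - oracle.x[0]) <= 0.01 + 1e-9
        assert abs(fit.sigma - oracle.x[1]) <= 0.01 + 1e-9

    def test_grid_matches_continuous_oracle_on_random_histograms(self):
        rng = np.random.default_rng(77)
        est = GridSearchGaussian()
        for _ in range(20):
            length = int(rng.integers(4, 9))
            mu = rng.uniform(1.5, length - 0.5)
            sigma = rng.uniform(0.6, 2.5)
            counts = np.bincount(
                np.clip(np.round(rng.normal(mu, sigma, 2000)), 1, length).astype(int),
                minlength=length + 1,
            )[1:]
            fit = est.fit(counts, length)

            def objective(p):
                return est.chi2_surface(p[0], p[1], counts)

            bounds = [(0.5, length + 0.5), (0.3, 5.0)]  # same domain as the grid
            oracle = min(
                (
                    minimize(objective, [m0, s0], method="Nelder-Mead", bounds=bounds)
                    for m0 in np.clip(
                        [fit.mu_ - 0.5, fit.mu_, fit.mu_ + 0.5], 0.5, length + 0.5
                    )
                    for s0 in np.clip(
                        [fit.sigma_ - 0.3, fit.sigma_, fit.sigma_ + 0.3], 0.31, 5.0
                    )
                ),
                key=lambda r: r.fun,
            )
            assert abs(fit.mu_ - oracle.x[0]) <= 0.011
            assert abs(fit.sigma_ - oracle.x[1]) <= 0.011

    def test_symmetric_histogram_centers_mu(self):
        fit = fit_gaussian_gridsearch(np.array([5, 20, 50, 20, 5]), 5)
        assert fit.mu == pytest.approx(3.0, abs=0.011)

    def test_deterministic(self):
        counts = discretized_counts(2.5, 1.0, 5, 500)
        a = fit_gaussian_gridsearch(counts, 5)
        b = fit_gaussian_gridsearch(counts, 5)
        assert (a.mu, a.sigma) == (b.mu, b.sigma)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gaussian_gridsearch(np.array([0, 10, 0, 0]), 4)
        with pytest.raises(ValueError, match="all-zero"):
            fit_gaussian_gridsearch(np.zeros(4), 4)


class TestLaunchSiteRegression:
    def test_exact_line_inversion(self):
        L = np.array([1.0, 2, 3, 4, 5, 6])
        delta = 0.5 * (4.0 - L)
        reg = LaunchSiteRegression().fit(L, delta)
        assert reg.lambda_ == pytest.approx(0.5, abs=1e-10)
        assert reg.L0_ == pytest.approx(4.0, abs=1e-8)

    def test_flat_case_has_undefined_L0(self):
        reg = LaunchSiteRegression().fit([1.0, 2, 3, 4], np.zeros(4))
        assert reg.lambda_ == pytest.approx(0.0, abs=1e-12)
        assert reg.L0_ is None

    def test_matches_hand_rolled_normal_equations(self):
        rng = np.random.default_rng(3)
        L = rng.uniform(1, 8, 12)
        d = -0.4 * L + 1.5 + rng.normal(0, 0.1, 12)
        w = rng.integers(5, 50, 12).astype(float)
        reg = LaunchSiteRegression().fit(L, d, sample_weight=w)
        # weighted normal equations oracle
        X = np.column_stack([np.ones_like(L), L])
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ d)
        assert reg.lambda_ == pytest.approx(-beta[1], abs=1e-10)
        assert reg.L0_ == pytest.approx(beta[0] / -beta[1], abs=1e-8)

    def test_too_few_launch_bins_raise(self):
        with pytest.raises(ValueError):
            LaunchSiteRegression().fit([1.0, 1.0, 2.0], [0.1, 0.2, 0.3])


class TestRecoveryFromForcedLaunchSaccades:
    def test_slope_and_intercept_recovered(self):
        sacc = sample_forward_saccades(20_000, 0.37, 4.0, 1.2, seed=11)
        fit = fit_landing_function(landing_cells(sacc))
        assert fit.lam_ci[0] <= 0.37 <= fit.lam_ci[1]
        assert abs(fit.lam - 0.37) < 0.02
        assert fit.L0 == pytest.approx(4.0, abs=3 * fit.L0_se)

    def test_slope_estimates_variance_ratio(self):
        """Data generated under the Bayes-model variance ratio r yields a
        fitted slope converging to r."""
        s0_sq, sT_sq = 1.0, 1.5
        r = s0_sq / (s0_sq + sT_sq)
        sacc = sample_forward_saccades(50_000, r, 4.0, 1.2, seed=21)
        fit = fit_landing_function(landing_cells(sacc))
        assert abs(fit.lam - r) < 0.02


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(n_subjects=1, n_trials=500, seed=29)
    fx, words = simulate_experiment(cfg)
    events = classify_saccades(fx)
    return fx, words, events


class TestPipelineTables:
    def test_word_centers_reconstruction(self):
        words = pd.DataFrame(
            {
                "subject": 1, "session": 1, "trial": 1,
                "word_index": [1, 2, 3], "word_length": [2, 3, 4],
            }
        )
        w = word_centers(words)
        assert list(w["first_char_col"]) == [1, 4, 8]
        assert list(w["center_col"]) == [1.5, 5.0, 9.5]

    def test_forward_table_properties(self, sim):
        fx, words, events = sim
        sacc = forward_saccade_table(events, fx, words)
        assert (sacc["launch_dist"] > 0).all()
        assert len(sacc) <= (events["type"] == "forward").sum()

    def test_launch_restriction_filters_distant_launches(self, sim):
        fx, words, events = sim
        sacc = forward_saccade_table(events, fx, words)
        cells_all = landing_cells(sacc, min_cell_n=1)
        cells_near = landing_cells(sacc, min_cell_n=1, restrict_launch=5)
        assert cells_near["n"].sum() < cells_all["n"].sum()
        assert (sacc["launch_from_beginning"] <= 5).sum() == cells_near["n"].sum()

    def test_histogram_matches_discretized_gaussian(self):
        """Simulated single-word landings follow the discretized Gaussian."""
        rng = np.random.default_rng(55)
        length, mu, sigma = 7, 4.0, 1.2
        n = 5000
        letters = np.clip(np.round(rng.normal(mu, sigma, n)), 1, length).astype(int)
        obs = np.bincount(letters, minlength=length + 1)[1:]
        edges = np.arange(1.5, length + 0.5)
        inner = np.diff(ndtr((edges - mu) / sigma))
        p = np.concatenate(
            [[ndtr((1.5 - mu) / sigma)], inner, [1 - ndtr((length - 0.5 - mu) / sigma)]]
        )
        stat, pval = chisquare(obs, p * n)
        assert pval > 1e-3

    def test_select_landing_letters_selections(self, sim):
        fx, words, events = sim
        single = select_landing_letters(fx, words, 6, "single")
        fwd = select_landing_letters(fx, words, 6, "forward")
        assert len(single) > 0 and len(fwd) > 0
        assert set(single) <= set(range(1, 7))
        unlimited = select_landing_letters(fx, words, 6, "single", launch_limit=None)
        assert len(unlimited) >= len(single)


class TestSDProfile:
    def test_two_point_cell(self):
        sacc = pd.DataFrame(
            {
                "word_length": [5] * 4,
                "launch_dist": [3.0, 3.0, 4.0, 4.0],
                "landing": [-1.0, 1.0, -1.0, 1.0],
                "launch_from_beginning": [1.0] * 4,
            }
        )
        table, grand = landing_sd_profile(sacc)
        assert table["sd"].iloc[0] == pytest.approx(np.sqrt(2))
        assert grand == pytest.approx(np.sqrt(2))

    def test_motor_noise_recovered(self):
        sacc = sample_forward_saccades(30_000, 0.37, 4.0, 1.5, seed=6)
        table, grand = landing_sd_profile(sacc)
        assert grand == pytest.approx(1.5, abs=0.05)

    def test_near_noiseless_generator_gives_near_zero_sd(self):
        sacc = sample_forward_saccades(2000, 0.37, 4.0, 1e-6, seed=6)
        _, grand = landing_sd_profile(sacc)
        assert grand < 1e-5

    def test_all_small_cells_raise(self):
        sacc = pd.DataFrame(
            {
                "word_length": [5],
                "launch_dist": [3.0],
                "landing": [0.0],
                "launch_from_beginning": [1.0],
            }
        )
        with pytest.raises(ValueError):
            landing_sd_profile(sacc)
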