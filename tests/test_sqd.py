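"""Square-displacement mixture decomposition, model selection, global fit
and the jump-distance goodness check."""

import numpy as np
import pytest

from sptkin import (
    SQDSample,
    TrackSimParams,
    compute_sqd,
    fit_jump_distance,
    fit_sqd_mixture,
    global_fit_sqd,
    select_model,
    simulate_tracks,
)
from sptkin.sqd import GlobalSQDModel
from sptkin.tracks import Track, TrackSet, filter_tracks

TAU = 0.024


def exponential_mixture_draws(rng, means, fractions, n):
    """Direct draws of squared displacements from a k-state mixture."""
    which = rng.choice(len(means), size=n, p=fractions)
    return rng.exponential(np.asarray(means)[which])


def mle_grid_search(x, tau, k):
    """Brute-force maximum-likelihood grid search over (D..., f).

    Independent oracle for the least-squares CDF fit: evaluates the
    exponential-mixture log-likelihood on a log-spaced D grid (60 points
    spanning the data) and, for k = 2, a fraction grid of 0.05 steps.
    Returns (d_sorted_desc, fractions, grid_log_step).
    """
    d_grid = np.geomspace(np.quantile(x, 0.005) / (4 * tau),
                          np.quantile(x, 0.999) / (4 * tau), 60)
    log_step = np.log(d_grid[1] / d_grid[0])
    dens = np.exp(-x[None, :] / (4 * d_grid[:, None] * tau)) / (4 * d_grid[:, None] * tau)
    if k == 1:
        ll = np.sum(np.log(dens + 1e-300), axis=1)
        i = int(np.argmax(ll))
        return np.array([d_grid[i]]), np.array([1.0]), log_step
    f_grid = np.arange(0.05, 1.0, 0.05)
    best = (-np.inf, None)
    for i in range(len(d_grid)):
        for j in range(i):
            mix = f_grid[:, None] * dens[i][None, :] + (1 - f_grid)[:, None] * dens[j][None, :]
            lls = np.sum(np.log(mix + 1e-300), axis=1)
            m = int(np.argmax(lls))
            if lls[m] > best[0]:
                best = (lls[m], (d_grid[i], d_grid[j], f_grid[m]))
    d1, d2, f1 = best[1]
    return np.array([d1, d2]), np.array([f1, 1 - f1]), log_step


class TestSqdSample:
    def test_two_point_empirical_cdf(self):
        s = SQDSample(lag=TAU, sq_displacements=np.array([2.0, 1.0]), n=0)
        np.testing.assert_allclose(s.sq_displacements, [1.0, 2.0])
        np.testing.assert_allclose(s.empirical_cdf, [0.5, 1.0])

    def test_compute_sqd_pools_only_exact_lag_pairs(self):
        # gap between frames 1 and 3 must not contribute a lag-1 pair
        t = Track(track_id=0, frames=np.array([0, 1, 3, 4, 5]),
                  x=np.array([0.0, 0.1, 5.0, 5.1, 5.2]), y=np.zeros(5))
        ts = TrackSet(tracks=[t], frame_interval=TAU)
        s = compute_sqd(ts, lag=1, exclude_last_point=False)
        np.testing.assert_allclose(np.sort(s.sq_displacements), [0.01, 0.01, 0.01])

    def test_empty_sample_raises(self):
        t = Track(track_id=0, frames=np.array([0, 2]), x=np.zeros(2), y=np.zeros(2))
        ts = TrackSet(tracks=[t], frame_interval=TAU)
        with pytest.raises(ValueError, match="no displacement pairs"):
            compute_sqd(ts, lag=1)

    def test_small_sample_warns(self):
        t = Track(track_id=0, frames=np.arange(10), x=np.linspace(0, 1, 10),
                  y=np.zeros(10))
        ts = TrackSet(tracks=[t], frame_interval=TAU)
        with pytest.warns(UserWarning, match="unreliable"):
            compute_sqd(ts, lag=1)

    def test_empirical_cdf_within_dkw_band_of_true_cdf(self):
        """Single-state draws stay inside the 99% DKW envelope."""
        d = 0.2
        params = TrackSimParams(diffusion_constants=(d,), fractions=(1.0,),
                                n_tracks=2000, localization_sigma=0.0, seed=21)
        s = compute_sqd(simulate_tracks(params), lag=1)
        true_cdf = 1 - np.exp(-s.sq_displacements / (4 * d * TAU))
        eps = np.sqrt(np.log(2 / 0.01) / (2 * s.n))
        assert np.max(np.abs(s.empirical_cdf - true_cdf)) < eps + 1 / s.n


class TestMixtureFit:
    def test_exact_single_exponential_inverted(self):
        """Noiseless CDF points are inverted to the generating D and ~0 rss."""
        d, n = 0.25, 2000
        m = 4 * d * TAU
        ranks = np.arange(1, n)
        # place each point where the model CDF equals its empirical rank/n;
        # the top rank (CDF = 1) sits deep in the tail where e^(-x/m) ~ 1e-18
        x = np.append(-m * np.log1p(-ranks / n), 40 * m)
        fit = fit_sqd_mixture(SQDSample(lag=TAU, sq_displacements=x, n=0), k=1)
        assert fit.d_components[0] == pytest.approx(d, rel=1e-6)
        assert fit.rss < 1e-12

    def test_two_state_recovery_within_stated_tolerance(self):
        rng = np.random.default_rng(5)
        x = exponential_mixture_draws(
            rng, [4 * 1.0 * TAU, 4 * 0.01 * TAU], [0.5, 0.5], 10_000
        )
        fit = fit_sqd_mixture(SQDSample(lag=TAU, sq_displacements=x, n=0), k=2, seed=5)
        assert fit.d_components[0] == pytest.approx(1.0, rel=0.10)
        assert fit.d_components[1] == pytest.approx(0.01, rel=0.10)
        assert fit.fractions[0] == pytest.approx(0.5, abs=0.05)

    def test_fractions_sum_to_one_and_d_sorted(self):
        rng = np.random.default_rng(6)
        x = exponential_mixture_draws(
            rng, [4 * 0.5 * TAU, 4 * 0.02 * TAU], [0.7, 0.3], 5000
        )
        for k in (1, 2, 3):
            fit = fit_sqd_mixture(SQDSample(lag=TAU, sq_displacements=x, n=0),
                                  k=k, seed=6)
            assert fit.fractions.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(np.diff(fit.d_components) <= 1e-12)
            assert fit.n_params == 2 * k - 1

    def test_estimates_consistent_across_seeds(self):
        """Median |relative error| of each D < 10% over repeated datasets."""
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = exponential_mixture_draws(
                rng, [4 * 0.8 * TAU, 4 * 0.02 * TAU], [0.6, 0.4], 10_000
            )
            fit = fit_sqd_mixture(SQDSample(lag=TAU, sq_displacements=x, n=0),
                                  k=2, seed=seed)
            errs.append([abs(fit.d_components[0] - 0.8) / 0.8,
                         abs(fit.d_components[1] - 0.02) / 0.02])
        med = np.median(np.asarray(errs), axis=0)
        assert np.all(med < 0.10)

    @pytest.mark.parametrize("k,true_d,true_f", [
        (1, [0.3], [1.0]),
        (2, [0.5, 0.01], [0.6, 0.4]),
    ])
    def test_least_squares_agrees_with_mle_grid_oracle(self, k, true_d, true_f):
        """CDF least squares lands within grid resolution of brute-force MLE."""
        rng = np.random.default_rng(17 + k)
        x = exponential_mixture_draws(
            rng, [4 * d * TAU for d in true_d], true_f, 2000
        )
        sample = SQDSample(lag=TAU, sq_displacements=x, n=0)
        fit = fit_sqd_mixture(sample, k=k, seed=17)
        d_mle, f_mle, log_step = mle_grid_search(x, TAU, k)
        # agreement within two grid steps in log-D space
        np.testing.assert_allclose(
            np.log(fit.d_components), np.log(d_mle), atol=2 * log_step
        )
        if k == 2:
            assert fit.fractions[0] == pytest.approx(f_mle[0], abs=0.10)


class TestModelSelection:
    def test_single_state_keeps_one_component(self):
        rng = np.random.default_rng(31)
        x = rng.exponential(4 * 0.2 * TAU, size=5000)
        res = select_model(SQDSample(lag=TAU, sq_displacements=x, n=0), seed=31)
        assert res.selected_k == 1
        assert not res.comparisons[0].accepted

    def test_two_separated_states_selects_two(self):
        rng = np.random.default_rng(32)
        x = exponential_mixture_draws(
            rng, [4 * 1.0 * TAU, 4 * 0.01 * TAU], [0.5, 0.5], 5000
        )
        res = select_model(SQDSample(lag=TAU, sq_displacements=x, n=0), seed=32)
        assert res.selected_k == 2

    def test_three_state_track_mixture_selects_three(self):
        """A wild-type-like 3-state track set (fast/slow/immobile) yields k=3."""
        params = TrackSimParams(
            diffusion_constants=(0.479, 0.105, 0.0151),
            fractions=(0.477, 0.2615, 0.2615),
            n_tracks=3000, localization_sigma=0.0, seed=33,
        )
        ts = filter_tracks(simulate_tracks(params), 5, 0)
        res = select_model(compute_sqd(ts, lag=1), seed=33)
        assert res.selected_k == 3
        assert res.selected_fit.labels == ("fast mobile", "slow mobile", "immobile")

    def test_two_state_track_mixture_selects_two(self):
        """A condensin-like 2-state track set (slow/immobile) yields k=2."""
        params = TrackSimParams(
            diffusion_constants=(0.0982, 0.0141), fractions=(0.5, 0.5),
            n_tracks=3000, localization_sigma=0.0, seed=34,
        )
        ts = filter_tracks(simulate_tracks(params), 5, 0)
        res = select_model(compute_sqd(ts, lag=1), seed=34)
        assert res.selected_k == 2

    def test_selection_stops_at_first_rejection(self):
        rng = np.random.default_rng(35)
        x = rng.exponential(4 * 0.1 * TAU, size=3000)
        res = select_model(SQDSample(lag=TAU, sq_displacements=x, n=0), seed=35)
        # after rejecting k=2 no k=3 comparison is attempted
        assert len(res.comparisons) == 1


class TestGlobalFit:
    def test_identical_conditions_get_equal_fractions(self):
        rng = np.random.default_rng(41)
        x = exponential_mixture_draws(
            rng, [4 * 0.5 * TAU, 4 * 0.01 * TAU], [0.5, 0.5], 8000
        )
        s = SQDSample(lag=TAU, sq_displacements=x, n=0)
        gf = global_fit_sqd({"a": s, "b": s}, k=2, seed=41)
        np.testing.assert_allclose(gf.fractions["a"], gf.fractions["b"], atol=0.02)

    def test_shared_d_and_condition_fractions_recovered(self):
        rng = np.random.default_rng(42)
        means = [4 * 0.5 * TAU, 4 * 0.01 * TAU]
        xa = exponential_mixture_draws(rng, means, [0.7, 0.3], 10_000)
        xb = exponential_mixture_draws(rng, means, [0.3, 0.7], 10_000)
        gf = global_fit_sqd(
            {"a": SQDSample(lag=TAU, sq_displacements=xa, n=0),
             "b": SQDSample(lag=TAU, sq_displacements=xb, n=0)},
            k=2, seed=42,
        )
        assert gf.d_components[0] == pytest.approx(0.5, rel=0.10)
        assert gf.d_components[1] == pytest.approx(0.01, rel=0.10)
        assert gf.fractions["a"][0] == pytest.approx(0.7, abs=0.05)
        assert gf.fractions["b"][0] == pytest.approx(0.3, abs=0.05)

    def test_single_condition_reproduces_plain_fit(self):
        rng = np.random.default_rng(43)
        x = exponential_mixture_draws(
            rng, [4 * 0.4 * TAU, 4 * 0.02 * TAU], [0.5, 0.5], 4000
        )
        s = SQDSample(lag=TAU, sq_displacements=x, n=0)
        single = fit_sqd_mixture(s, k=2, seed=43)
        glob = global_fit_sqd({"only": s}, k=2, seed=43)
        np.testing.assert_allclose(glob.d_components, single.d_components, rtol=1e-6)
        np.testing.assert_allclose(glob.fractions["only"], single.fractions, atol=1e-6)

    def test_incompatible_lags_rejected(self):
        a = SQDSample(lag=TAU, sq_displacements=np.ones(100), n=0)
        b = SQDSample(lag=2 * TAU, sq_displacements=np.ones(100), n=0)
        with pytest.raises(ValueError, match="incompatible lags"):
            GlobalSQDModel({"a": a, "b": b}, k=1)

    def test_fast_fraction_ordering_preserved_across_conditions(self):
        """Conditions simulated at fast fractions 0.477 vs 0.152 keep their gap."""
        base = dict(diffusion_constants=(0.479, 0.105, 0.0151),
                    n_tracks=2500, localization_sigma=0.0)
        ts_hi = filter_tracks(simulate_tracks(
            TrackSimParams(fractions=(0.477, 0.2615, 0.2615), seed=44, **base)), 5, 0)
        ts_lo = filter_tracks(simulate_tracks(
            TrackSimParams(fractions=(0.152, 0.518, 0.33), seed=45, **base)), 5, 0)
        gf = global_fit_sqd(
            {"wt": compute_sqd(ts_hi), "plasmid": compute_sqd(ts_lo)}, k=3, seed=44
        )
        f_hi, f_lo = gf.fractions["wt"][0], gf.fractions["plasmid"][0]
        assert f_hi > f_lo
        assert f_hi - f_lo == pytest.approx(0.477 - 0.152, abs=0.10)


class TestJumpDistance:
    def test_self_consistency_on_single_state(self, single_state_tracks):
        sq = compute_sqd(single_state_tracks, lag=1)
        fit = fit_sqd_mixture(sq, k=1, seed=0)
        rep = fit_jump_distance(single_state_tracks, fit, lag=1)
        assert rep.r_squared >= 0.99

    def test_wrong_d_scores_worse_than_fitted_d(self, single_state_tracks):
        import dataclasses

        sq = compute_sqd(single_state_tracks, lag=1)
        fit = fit_sqd_mixture(sq, k=1, seed=0)
        wrong = dataclasses.replace(fit, d_components=fit.d_components * 10)
        good = fit_jump_distance(single_state_tracks, fit, lag=1)
        bad = fit_jump_distance(single_state_tracks, wrong, lag=1)
        assert bad.r_squared < good.r_squared

    def test_chi2_consistent_with_bin_noise_on_true_model(self, two_state_tracks):
        """Scoring a mixture against its own generating parameters gives a
        χ²/dof of order 1."""
        from sptkin.sqd import MixtureFit

        sq = compute_sqd(two_state_tracks, lag=1)
        truth = MixtureFit(
            k=2, d_components=np.array([1.0, 0.01]),
            fractions=np.array([0.5, 0.5]), sigma2_eff=0.0, lag=TAU,
            rss=0.0, n=sq.n, n_params=3, bic=0.0, loglik=0.0,
        )
        rep = fit_jump_distance(two_state_tracks, truth, lag=1)
        assert rep.chi2 / rep.dof < 2.0
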