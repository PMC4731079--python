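import numpy as np
import pytest
from scipy.stats import dirichlet as sp_dirichlet
from scipy.stats import kstest

from conftest import profiles_from
from ddpmix.hdp_patterns import (
    DEFAULT_INTERVALS,
    FinishTimePredictor,
    HDPPatternModel,
    _HDPPatternSampler,
    _PatternData,
    dirichlet_pattern_loglik,
    fit_hdp_patterns,
    normalize_splits,
    partial_profile_loglik,
)


class TestNormalizeSplits:
    def test_even_pacing_gives_equal_fractions(self):
        f = normalize_splits([20.0, 40.0, 60.0, 80.0])
        np.testing.assert_allclose(f, 0.25, atol=1e-12)

    def test_arithmetic(self):
        np.testing.assert_allclose(
            normalize_splits([30.0, 60.0, 120.0]), [0.25, 0.25, 0.5], atol=1e-12
        )

    def test_round_trip(self):
        cum = np.array([22.0, 47.5, 71.0, 103.2, 131.9])
        f = normalize_splits(cum)
        np.testing.assert_allclose(np.cumsum(f) * cum[-1], cum, atol=1e-9)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "bad", [[30.0, 25.0, 60.0], [0.0, 10.0], [10.0, np.nan, 30.0], [-5.0, 10.0]]
    )
    def test_invalid_records_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize_splits(bad)

    def test_scheme_length_checked(self):
        with pytest.raises(ValueError):
            normalize_splits([10.0, 20.0], DEFAULT_INTERVALS)


class TestDirichletLoglik:
    def test_uniform_case_is_zero(self):
        # Dirichlet(1, 1) is uniform on the 2-simplex interior
        for x in ([0.3, 0.7], [0.5, 0.5], [0.91, 0.09]):
            assert dirichlet_pattern_loglik(x, [0.5, 0.5], 2.0) == pytest.approx(0.0, abs=1e-10)

    def test_matches_scipy_density(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            p = rng.dirichlet(np.ones(4) * 2)
            x = rng.dirichlet(np.ones(4) * 3)
            tau = float(rng.uniform(10, 5000))
            got = dirichlet_pattern_loglik(x, p, tau)
            assert got == pytest.approx(sp_dirichlet.logpdf(x, tau * p), rel=1e-9)

    def test_integrates_to_one_on_3_simplex(self):
        # quadrature over the open simplex; concentration > 1 keeps the
        # boundary contribution negligible
        p = np.array([0.3, 0.3, 0.4])
        tau = 30.0
        h = 1 / 600
        g = np.arange(h / 2, 1.0, h)
        x1, x2 = np.meshgrid(g, g)
        keep = x1 + x2 < 1 - h / 2
        x1, x2 = x1[keep], x2[keep]
        pts = np.stack([x1, x2, 1 - x1 - x2], axis=1)
        vals = np.exp([dirichlet_pattern_loglik(q, p, tau) for q in pts])
        assert vals.sum() * h * h == pytest.approx(1.0, abs=1e-3)

    def test_boundary_pattern_rejected(self):
        with pytest.raises(ValueError):
            dirichlet_pattern_loglik([0.5, 0.5], [1.0, 0.0], 10.0)


class TestPartialProfile:
    def test_renormalized_head_follows_aggregated_dirichlet(self):
        # Monte-Carlo check of the aggregation identity: the first
        # coordinate of the renormalized head of Dir(tau p) is
        # Beta(tau p_1, tau p_2) when D = 2
        rng = np.random.default_rng(1)
        tau, p = 800.0, np.array([0.3, 0.25, 0.45])
        x = rng.dirichlet(tau * p, size=4000)
        head = x[:, :2] / x[:, :2].sum(axis=1, keepdims=True)
        stat = kstest(head[:, 0], "beta", args=(tau * p[0], tau * p[1]))
        assert stat.pvalue > 0.01

    def test_last_aggregation_equals_full_marginal(self):
        # D = D_total - 1: density of the renormalized head must equal the
        # Dirichlet obtained by aggregating the final two coordinates
        tau, p = 500.0, np.array([0.2, 0.3, 0.15, 0.35])
        obs = np.array([0.25, 0.35, 0.40])
        got = partial_profile_loglik(obs / obs.sum(), p, tau)
        expect = sp_dirichlet.logpdf(obs / obs.sum(), tau * p[:3])
        assert got == pytest.approx(expect, rel=1e-9)

    def test_single_cluster_membership_is_one(self):
        ll = partial_profile_loglik([0.4, 0.6], np.array([0.2, 0.3, 0.5]), 100.0)
        w = np.exp([ll])
        assert (w / w.sum())[0] == pytest.approx(1.0)

    def test_likelihood_dominance_for_matching_head(self):
        tau = 2000.0
        p1 = np.array([0.2, 0.3, 0.5])
        p2 = np.array([0.3, 0.2, 0.5])
        obs = p1[:2] / p1[:2].sum()
        l1 = partial_profile_loglik(obs, p1, tau)
        l2 = partial_profile_loglik(obs, p2, tau)
        prob1 = 1 / (1 + np.exp(l2 - l1))
        assert prob1 > 0.5

    def test_empty_observation_rejected(self):
        with pytest.raises(ValueError):
            partial_profile_loglik([], np.array([0.5, 0.5]), 10.0)


class TestPatternUpdates:
    def test_mh_chain_matches_grid_posterior(self):
        # single cluster, fixed assignments: the pattern chain must match a
        # finely discretised posterior on the 2-simplex
        rng = np.random.default_rng(2)
        tau = 200.0
        truth = np.array([0.45, 0.55])
        X = rng.dirichlet(tau * truth, size=20)
        data = _PatternData(X, np.zeros(len(X), dtype=int))
        from ddpmix.hdp_patterns import PatternConfig

        cfg = PatternConfig(
            tau=tau, epsilon=1.0, interval_lengths=(1.0, 1.0), n_iter=1, seed=3, init_clusters=1
        )
        s = _HDPPatternSampler(data, cfg, np.random.default_rng(3))
        draws = np.empty(40_000)
        for i in range(len(draws)):
            s.update_patterns()
            if i % 50 == 0:
                s.adapt_proposals()
            draws[i] = s.P[0][0]
        # grid posterior for p1 on (0, 1)
        grid = np.linspace(1e-4, 1 - 1e-4, 4000)
        logp = np.zeros_like(grid)
        logX = np.log(X)
        from scipy.special import gammaln

        for i, p1 in enumerate(grid):
            p = np.array([p1, 1 - p1])
            lik = len(X) * (gammaln(tau) - gammaln(tau * p).sum()) + (tau * p - 1) @ logX.sum(0)
            logp[i] = lik  # prior Dir(1,1) is flat
        pdf = np.exp(logp - logp.max())
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(draws[5000:]), grid) / len(draws[5000:])
        assert np.abs(emp - cdf).max() < 0.05

    def test_patterns_stay_on_simplex(self, split_cohort):
        df, _ = split_cohort
        prof, _, groups = profiles_from(df)
        model = HDPPatternModel(
            tau=5000.0, interval_lengths=(5, 5, 5, 5, 2.195), n_iter=120, thin=5, seed=4
        ).fit(prof[:200], groups[:200])
        for s in model.archive_.states:
            sums = s["patterns"].sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)
            assert np.all(s["patterns"] > 0)

    def test_sharp_likelihood_concentrates_on_common_profile(self):
        x_star = np.array([0.3, 0.3, 0.4])
        X = np.tile(x_star, (60, 1))
        model = HDPPatternModel(
            tau=50_000.0, interval_lengths=(1, 1, 1), n_iter=200, thin=5, seed=5, init_clusters=1
        ).fit(X, np.zeros(60, dtype=int))
        assert np.abs(model.patterns_[0] - x_star).max() < 0.005


class TestFitAndWeights:
    def test_exchangeable_groups_match(self, split_cohort):
        df, truth = split_cohort
        prof, _, _ = profiles_from(df)
        groups = np.arange(len(prof)) % 2  # identical mixing by construction
        model = HDPPatternModel(
            tau=5000.0, interval_lengths=(5, 5, 5, 5, 2.195), n_iter=400, thin=5, seed=6
        ).fit(prof, groups)
        gw = model.group_weights_
        # realized per-group cluster shares differ by O(sqrt(p(1-p)/n))
        # even under identical generative mixing; 3 sigma ~ 0.09
        np.testing.assert_allclose(gw[:, 0], gw[:, 1], atol=0.09)

    def test_higher_tau_never_coarsens_clustering(self, split_cohort):
        df, _ = split_cohort
        prof, _, groups = profiles_from(df)
        ks = []
        for tau in (2500.0, 10_000.0):
            m = HDPPatternModel(
                tau=tau, interval_lengths=(5, 5, 5, 5, 2.195), n_iter=400, thin=5, seed=7
            ).fit(prof, groups)
            ks.append(m.modal_n_clusters_)
        assert ks[1] >= ks[0]

    def test_fit_wrapper_archives(self, split_cohort):
        df, _ = split_cohort
        prof, _, groups = profiles_from(df)
        archive = fit_hdp_patterns(
            prof[:100], groups[:100], interval_lengths=(5, 5, 5, 5, 2.195), n_iter=40, thin=5, seed=8
        )
        assert archive.manifest["model"] == "hdp_patterns"
        assert len(archive) == 8


class TestPrediction:
    def test_full_observation_predicts_finish(self, split_cohort):
        df, _ = split_cohort
        _, cum, groups = profiles_from(df)
        pred = FinishTimePredictor(
            D=5, interval_lengths=(5, 5, 5, 5, 2.195), tau=5000.0, n_iter=100, seed=9
        ).fit(cum[:300], groups[:300])
        yhat = pred.predict(cum[300:340], groups[300:340])
        np.testing.assert_allclose(yhat, cum[300:340, -1], rtol=1e-9)

    def test_median_quotient_projection(self):
        # quotients {2.0, 2.1, 2.2} in a single cluster, elapsed 100 -> 210
        cum = np.array([[100.0, 200.0], [100.0, 210.0], [100.0, 220.0]])
        pred = FinishTimePredictor(
            D=1,
            interval_lengths=(1.0, 1.0),
            tau=100.0,
            n_iter=40,
            seed=10,
            alpha_prior_scale=1e-3,  # pin the posterior to a single cluster
        ).fit(cum, np.zeros(3, dtype=int))
        res = pred.predict_detailed(np.array([[100.0]]), [0])[0]
        assert res.predicted_finish == pytest.approx(210.0, rel=1e-9)
        assert res.membership_probs.sum() == pytest.approx(1.0)

    def test_scale_equivariance_exact(self, split_cohort):
        df, _ = split_cohort
        _, cum, groups = profiles_from(df)
        pred = FinishTimePredictor(
            D=2, interval_lengths=(5, 5, 5, 5, 2.195), tau=5000.0, n_iter=100, seed=11
        ).fit(cum[:300], groups[:300])
        base = pred.predict(cum[300:320, :2], groups[300:320])
        scaled = pred.predict(2.5 * cum[300:320, :2], groups[300:320])
        np.testing.assert_allclose(scaled, 2.5 * base, rtol=1e-12)

    def test_prediction_never_below_elapsed(self, split_cohort):
        df, _ = split_cohort
        _, cum, groups = profiles_from(df)
        pred = FinishTimePredictor(
            D=3, interval_lengths=(5, 5, 5, 5, 2.195), tau=5000.0, n_iter=100, seed=12
        ).fit(cum[:300], groups[:300])
        yhat = pred.predict(cum[300:350, :3], groups[300:350])
        assert np.all(yhat >= cum[300:350, 2])

    def test_invalid_D_rejected(self, split_cohort):
        df, _ = split_cohort
        _, cum, groups = profiles_from(df)
        with pytest.raises(ValueError):
            FinishTimePredictor(D=9, interval_lengths=(5, 5, 5, 5, 2.195)).fit(cum, groups)


def test_predict_finish_wrapper(split_cohort):
    from ddpmix.hdp_patterns import predict_finish

    df, _ = split_cohort
    prof, cum, groups = profiles_from(df)
    results = predict_finish(
        cum[300:310, :2],
        groups[300:310],
        cum[:300],
        groups[:300],
        D=2,
        interval_lengths=(5, 5, 5, 5, 2.195),
        tau=5000.0,
        n_iter=80,
        seed=14,
    )
    assert len(results) == 10
    assert all(r.predicted_finish >= cum[300 + i, 1] for i, r in enumerate(results))
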