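import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from ddpmix.addp import (
    ADDPMixture,
    _ADDPData,
    _ADDPSampler,
    addp_loglik,
    fit_addp,
    gp_shift_conditional,
    normal_mean_conditional,
    paper_hyperparameters,
    variance_conditional,
)
from ddpmix.bnp_core import KernelSpec, build_kernel


class TestLoglik:
    def test_density_at_the_mean(self):
        sigma2 = 4.0
        val = addp_loglik(10.0, 0, [7.0], [3.0], sigma2, variant="basic", group=0)
        assert val == pytest.approx(-0.5 * math.log(2 * math.pi * sigma2), abs=1e-12)

    def test_male_interaction_equals_basic(self):
        args = dict(mu=[200.0], theta=[5.0], sigma_x2=36.0, group=0)
        basic = addp_loglik(215.0, 0, variant="basic", **args)
        inter = addp_loglik(
            215.0, 0, variant="interaction", gender=0, delta=30.0, omega=[4.0], **args
        )
        assert inter == pytest.approx(basic, abs=1e-14)

    def test_matches_independent_gaussian_density(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            mu = rng.normal(200, 50, size=3)
            theta = rng.normal(0, 10, size=4)
            s2 = float(rng.uniform(1, 100))
            x = float(rng.normal(220, 60))
            k, j = int(rng.integers(3)), int(rng.integers(4))
            got = addp_loglik(x, k, mu, theta, s2, variant="basic", group=j)
            assert got == pytest.approx(norm.logpdf(x, mu[k] + theta[j], math.sqrt(s2)), rel=1e-12)

    def test_cluster_dependent_shift(self):
        theta_jk = np.array([[1.0, -2.0], [0.5, 3.0]])
        got = addp_loglik(
            100.0, 1, [95.0, 99.0], theta_jk, 9.0, variant="cluster_shifts", group=1
        )
        assert got == pytest.approx(norm.logpdf(100.0, 99.0 + 3.0, 3.0), rel=1e-12)


class TestClosedFormConditionals:
    """Each Gibbs block's conditional against independently coded formulas."""

    def test_cluster_mean_conditional(self):
        n_k, rsum, s2, mu0, s0 = 7, 1432.5, 36.0, 300.0, 3600.0
        mean, var = normal_mean_conditional(n_k, rsum, s2, mu0, s0)
        prec = 1 / s0 + n_k / s2
        assert var == pytest.approx(1 / prec, abs=1e-12)
        assert mean == pytest.approx((mu0 / s0 + rsum / s2) / prec, abs=1e-10)

    def test_cluster_mean_no_data_is_prior(self):
        mean, var = normal_mean_conditional(0, 0.0, 25.0, 300.0, 3600.0)
        assert (mean, var) == (300.0, 3600.0)

    def test_cluster_mean_concentrates_on_residual_mean(self):
        mean, var = normal_mean_conditional(10**7, 2.5e8, 36.0, 300.0, 3600.0)
        assert mean == pytest.approx(25.0, rel=1e-5)
        assert var < 1e-5

    def test_gp_shift_conditional_matches_direct_inversion(self):
        rng = np.random.default_rng(1)
        K = build_kernel(np.array([30.0, 31, 33, 40]), KernelSpec(180.0, 10.0, 1e-4))
        counts = np.array([5.0, 0.0, 12.0, 3.0])
        sums = rng.normal(0, 50, size=4)
        s2 = 30.0
        mean, cov = gp_shift_conditional(K, counts, sums, s2)
        prec = np.linalg.inv(K) + np.diag(counts / s2)
        cov_expect = np.linalg.inv(prec)
        np.testing.assert_allclose(cov, cov_expect, atol=1e-10)
        np.testing.assert_allclose(mean, cov_expect @ (sums / s2), atol=1e-10)

    def test_gp_shift_prior_mean_enters(self):
        K = build_kernel(np.array([30.0, 35.0]), KernelSpec(100.0, 10.0, 1e-6))
        pm = np.array([3.0, -4.0])
        mean, cov = gp_shift_conditional(K, np.zeros(2), np.zeros(2), 1.0, prior_mean=pm)
        np.testing.assert_allclose(mean, pm, atol=1e-8)
        np.testing.assert_allclose(cov, K, atol=1e-8)

    def test_gp_shift_huge_group_shrinks_neighbors(self):
        # one loaded group pins its own shift; neighbors move toward it in
        # proportion to the kernel correlation
        K = build_kernel(np.array([30.0, 31.0, 60.0]), KernelSpec(100.0, 10.0, 1e-8))
        counts = np.array([1e7, 0.0, 0.0])
        sums = np.array([1e7 * 8.0, 0.0, 0.0])
        mean, _ = gp_shift_conditional(K, counts, sums, 25.0)
        assert mean[0] == pytest.approx(8.0, rel=1e-4)
        assert mean[1] == pytest.approx(8.0 * K[0, 1] / K[0, 0], rel=1e-3)
        assert abs(mean[2]) < abs(mean[1])

    def test_variance_conditional(self):
        shape, scale = variance_conditional(100, 5000.0, 1.0, 3600.0)
        assert shape == pytest.approx(51.0)
        assert scale == pytest.approx(3600.0 + 2500.0)
        assert variance_conditional(0, 0.0, 1.0, 2.0) == (1.0, 2.0)

    def test_gender_effect_uses_same_normal_normal_form(self):
        # delta | rest is the scalar case with prior N(0, sigma_g^2)
        mean, var = normal_mean_conditional(50, 1500.0, 36.0, 0.0, 180.0)
        prec = 1 / 180.0 + 50 / 36.0
        assert var == pytest.approx(1 / prec, abs=1e-12)
        assert mean == pytest.approx((1500.0 / 36.0) / prec, abs=1e-10)

    def test_duplicate_positions_without_jitter_fail(self):
        K = build_kernel(np.array([30.0, 30.0]), KernelSpec(100.0, 10.0, 0.0))
        with pytest.raises(np.linalg.LinAlgError):
            gp_shift_conditional(K, np.ones(2), np.ones(2), 1.0)


class TestSamplerMechanics:
    def _tiny_sampler(self, x, alpha=1.0, seed=0, **cfg_kw):
        df = pd.DataFrame({"finish_time": x, "age": 30, "gender": 0})
        est = ADDPMixture(
            variant="basic",
            mu0=float(np.mean(x)),
            sigma0_sq=400.0,
            fixed_sigma_x2=1.0,
            sample_variance=False,
            sample_shifts=False,
            sample_alpha=False,
            n_iter=1,
            seed=seed,
            **cfg_kw,
        )
        data = _ADDPData(df, "basic")
        sampler = _ADDPSampler(data, est._config(), np.random.default_rng(seed))
        sampler.alpha = alpha
        return sampler

    def test_vanishing_alpha_keeps_single_cluster(self):
        s = self._tiny_sampler([10.0], alpha=1e-12, init_clusters=1)
        for _ in range(200):
            s.update_assignments()
        assert len(s.occ) == 1

    def test_two_lumps_separate(self, two_lump_data):
        df, truth = two_lump_data
        model = ADDPMixture(variant="basic", n_iter=400, thin=10, seed=2).fit(df)
        assert model.n_clusters_ == 2
        th0 = truth["theta"]["0"][0]
        expected = np.array(truth["true_means"]) + th0
        assert np.abs(model.cluster_means_ - expected).max() < 3.0
        # modal partition separates the lumps
        last = model.archive_.states[-1]
        lump = np.array(truth["assignments"])
        a = last["assignments"]
        agree = max(np.mean((a == a[lump == 0][0]) == (lump == 0)), 0)
        assert agree > 0.95

    def test_seed_determinism(self, two_lump_data):
        df, _ = two_lump_data
        m1 = ADDPMixture(variant="basic", n_iter=60, thin=5, seed=9).fit(df)
        m2 = ADDPMixture(variant="basic", n_iter=60, thin=5, seed=9).fit(df)
        for s1, s2 in zip(m1.archive_.states, m2.archive_.states):
            np.testing.assert_array_equal(s1["mu"], s2["mu"])
            np.testing.assert_array_equal(s1["assignments"], s2["assignments"])

    def test_archived_means_sorted_ascending(self, two_lump_data):
        df, _ = two_lump_data
        model = ADDPMixture(variant="basic", n_iter=100, thin=5, seed=3).fit(df)
        for s in model.archive_.states:
            assert np.all(np.diff(s["mu"]) >= 0)

    def test_empty_groups_get_imputed_shifts(self):
        # ages 30-32 exist for men only, 40-42 for women only: half the
        # (gender, age) grid is empty yet theta must be finite everywhere
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "finish_time": rng.normal(240, 10, 60),
                "age": np.r_[np.repeat([30, 31, 32], 10), np.repeat([40, 41, 42], 10)],
                "gender": np.r_[np.zeros(30, int), np.ones(30, int)],
            }
        )
        model = ADDPMixture(variant="basic", n_iter=50, thin=5, seed=5).fit(df)
        assert len(model.theta_) == 12  # 2 genders x 6 ages
        assert np.all(np.isfinite(model.theta_))

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            ADDPMixture(n_iter=10).fit(pd.DataFrame({"finish_time": []}))

    def test_relabeling_preserves_likelihood(self, two_lump_data):
        from ddpmix.postprocess import relabel_archive

        df, _ = two_lump_data
        model = ADDPMixture(variant="basic", n_iter=60, thin=5, seed=6).fit(df)
        rel = relabel_archive(model.archive_)
        for s0, s1 in zip(model.archive_.states, rel.states):
            np.testing.assert_allclose(
                np.sort(s0["mu"]), np.sort(s1["mu"][np.isfinite(s1["mu"])]), atol=1e-12
            )


class TestHierarchical:
    def test_single_race_matches_basic_statistically(self, two_lump_data):
        df, truth = two_lump_data
        basic = ADDPMixture(variant="basic", n_iter=500, thin=10, seed=7).fit(df)
        hier = ADDPMixture(variant="hierarchical", n_iter=500, thin=10, seed=8).fit(df)
        assert hier.n_clusters_ == basic.n_clusters_ == 2
        assert np.abs(basic.cluster_means_ - hier.cluster_means_).max() < 2.5
        assert abs(basic.sigma_x_ - hier.sigma_x_) < 1.0

    def test_two_races_share_clusters_with_own_weights(self):
        from ddpmix.synthetic import FinishTimeSpec, gen_finish_times

        spec = FinishTimeSpec(
            true_means=(180.0, 240.0),
            true_weights=(0.5, 0.5),
            ages=range(30, 34),
            genders=(0,),
            noise_sd=6.0,
            n_per_group=80,
            races=("A", "B"),
            race_weights=((0.75, 0.25), (0.25, 0.75)),
            seed=5,
        )
        df, truth = gen_finish_times(spec)
        model = ADDPMixture(variant="hierarchical", n_iter=900, thin=10, seed=7).fit(df)
        assert model.n_clusters_ == 2
        win = model.archive_.window()
        pis = [s["pi_r"] for s in win if s["pi_r"] is not None and s["pi_r"].shape[1] == 3]
        assert pis, "no two-cluster states with race weights in the window"
        pi = np.mean(pis, axis=0)
        # race A leans to the fast cluster, race B to the slow one
        assert pi[0, 0] > 0.6 and pi[1, 1] > 0.6

    def test_exchangeable_races_get_matching_weights(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(200, 5, 150), rng.normal(250, 5, 150)])
        df = pd.DataFrame(
            {
                "finish_time": np.tile(x, 2),
                "age": 30,
                "gender": 0,
                "race": np.repeat(["A", "B"], 300),
            }
        )
        model = ADDPMixture(variant="hierarchical", n_iter=600, thin=10, seed=12).fit(df)
        win = model.archive_.window()
        pis = [s["pi_r"] for s in win if s["pi_r"] is not None and s["pi_r"].shape[1] == 3]
        pi = np.mean(pis, axis=0)
        np.testing.assert_allclose(pi[0], pi[1], atol=0.05)


class TestConfigSurface:
    def test_paper_hyperparameters_scale(self):
        h = paper_hyperparameters("hours")
        m = paper_hyperparameters("minutes")
        assert m["mu0"] == h["mu0"] * 60
        assert m["sigma0_sq"] == h["sigma0_sq"] * 3600
        assert m["b"] == h["b"] * 3600
        assert m["kernel_lengthscale"] == h["kernel_lengthscale"]

    def test_prior_scale_ordering_enforced(self):
        with pytest.raises(ValueError, match="sigma0_sq"):
            ADDPMixture(sigma0_sq=10.0, kernel_variance=180.0, n_iter=10).fit(
                pd.DataFrame({"finish_time": [200.0], "age": [30], "gender": [0]})
            )

    def test_sklearn_params_roundtrip(self):
        est = ADDPMixture(variant="interaction", n_iter=123)
        params = est.get_params()
        est2 = ADDPMixture(**params)
        assert est2.get_params() == params

    def test_fit_addp_wrapper(self, two_lump_data):
        df, _ = two_lump_data
        archive = fit_addp(df, n_iter=40, thin=5, seed=1)
        assert archive.manifest["variant"] == "basic"
        assert len(archive) == 40 // 5


class TestScoreSamples:
    def test_density_higher_near_cluster_centres(self, two_lump_data):
        df, _ = two_lump_data
        model = ADDPMixture(variant="basic", n_iter=300, thin=10, seed=13).fit(df)
        near = pd.DataFrame({"finish_time": [model.cluster_means_[0]], "age": [30], "gender": [0]})
        far = pd.DataFrame({"finish_time": [500.0], "age": [30], "gender": [0]})
        assert model.score_samples(near)[0] > model.score_samples(far)[0]
        assert np.isfinite(model.score_samples(df)).all()
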