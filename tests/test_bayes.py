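"""Log posterior, gradient, HMC sampler and trajectory fits."""

import numpy as np
import pytest
import scipy.stats as sps

from cogtraj import (
    Cohort,
    GeneratorParams,
    McmcConfig,
    Participant,
    PriorSpec,
    SplineSpec,
    fit_group_trajectories,
    generate_cohort,
    hmc_sample,
    load_fit,
    make_log_posterior,
    posterior_curves,
    rcs_design,
    save_fit,
)


def term_by_term_log_posterior(theta, Xa, ya, Xb, yb, coef_scale, sigma_scale):
    """Independent summation with scipy distributions (free-σ Cauchy model)."""
    p = Xa.shape[1]
    beta_a, beta_b, lam = theta[:p], theta[p : 2 * p], theta[-1]
    sigma = np.exp(lam)
    total = 0.0
    for X, y, beta in ((Xa, ya, beta_a), (Xb, yb, beta_b)):
        for xi, yi in zip(X, y):
            total += sps.norm.logpdf(yi, loc=xi @ beta, scale=sigma)
        for bj in beta:
            total += sps.cauchy.logpdf(bj, scale=coef_scale)
    total += sps.halfcauchy.logpdf(sigma, scale=sigma_scale) + lam
    return total


@pytest.fixture
def tiny_model():
    rng = np.random.default_rng(0)
    Xa = np.column_stack([np.ones(3), rng.normal(size=3)])
    Xb = np.column_stack([np.ones(3), rng.normal(size=3)])
    ya = np.array([27.0, 24.5, 11.0])
    yb = np.array([29.0, 28.0, 30.0])
    priors = PriorSpec(coef_scale=2.5, sigma_scale=5.0, autoscale=False)
    logpost, dim = make_log_posterior(Xa, ya, Xb, yb, priors)
    return logpost, dim, (Xa, ya, Xb, yb)


class TestLogPosterior:
    def test_matches_independent_summation(self, tiny_model):
        logpost, dim, (Xa, ya, Xb, yb) = tiny_model
        theta = np.array([25.0, -0.5, 29.0, 0.1, np.log(2.0)])
        lp, _ = logpost(theta)
        expected = term_by_term_log_posterior(theta, Xa, ya, Xb, yb, 2.5, 5.0)
        assert lp == pytest.approx(expected, rel=1e-12)

    def test_zero_rows_gives_prior_only(self):
        priors = PriorSpec(autoscale=False)
        logpost, dim = make_log_posterior(
            np.empty((0, 2)), np.empty(0), np.empty((0, 2)), np.empty(0), priors
        )
        theta = np.array([1.0, -2.0, 0.5, 0.0, np.log(3.0)])
        lp, _ = logpost(theta)
        expected = sum(
            sps.cauchy.logpdf(b, scale=2.5) for b in theta[:4]
        ) + sps.halfcauchy.logpdf(3.0, scale=5.0) + np.log(3.0)
        assert lp == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_gradient_matches_central_differences(self, tiny_model, seed):
        logpost, dim, _ = tiny_model
        rng = np.random.default_rng(seed)
        theta = rng.normal(0, 2, size=dim)
        theta[-1] = rng.uniform(-0.5, 1.5)  # keep σ on a scale where the
        # finite-difference oracle itself is accurate
        _, grad = logpost(theta)
        h = 1e-6
        for j in range(dim):
            e = np.zeros(dim)
            e[j] = h
            numeric = (logpost(theta + e)[0] - logpost(theta - e)[0]) / (2 * h)
            assert abs(grad[j] - numeric) < 1e-5

    def test_non_finite_input_errors(self, tiny_model):
        logpost, dim, _ = tiny_model
        with pytest.raises(ValueError):
            logpost(np.full(dim, np.nan))


class TestHmcSampler:
    def test_standard_normal_target(self):
        """2-d standard normal: mean within 3·MCSE of 0, covariance within
        10% of identity at ≈4000 retained draws."""

        def target(theta):
            return -0.5 * float(theta @ theta), -theta

        config = McmcConfig(chains=4, iterations=2000, thin=1, n_leapfrog=10, seed=5)
        draws, info = hmc_sample(target, 2, config)
        flat = draws.reshape(-1, 2)
        assert flat.shape[0] == 4000
        mcse = flat.std(axis=0) / np.sqrt(flat.shape[0] / 10)  # conservative ESS
        assert np.all(np.abs(flat.mean(axis=0)) < 3 * mcse)
        cov = np.cov(flat.T)
        assert np.abs(cov - np.eye(2)).max() < 0.1

    def test_same_seed_identical_draws(self):
        def target(theta):
            return -0.5 * float(theta @ theta), -theta

        config = McmcConfig(chains=2, iterations=400, thin=2, seed=9)
        d1, _ = hmc_sample(target, 3, config)
        d2, _ = hmc_sample(target, 3, config)
        assert np.array_equal(d1, d2)

    def test_conjugate_gaussian_fixed_sigma(self):
        """Gaussian-prior/fixed-σ variant: HMC posterior mean matches the
        closed-form ridge solution within 3·MCSE per coefficient."""
        rng = np.random.default_rng(12)
        n, p = 50, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        beta_true = np.array([20.0, -2.0, 1.0])
        sigma = 2.0
        y = X @ beta_true + rng.normal(0, sigma, n)
        prior_sd = 10.0
        priors = PriorSpec(coef_scale=prior_sd, family="gaussian", autoscale=False)
        logpost, dim = make_log_posterior(X, y, X, y, priors, sigma_fixed=sigma)

        precision = X.T @ X / sigma**2 + np.eye(p) / prior_sd**2
        exact_mean = np.linalg.solve(precision, X.T @ y / sigma**2)

        config = McmcConfig(chains=4, iterations=3000, thin=1, n_leapfrog=15, seed=4)
        draws, _ = hmc_sample(logpost, dim, config, init=np.zeros(dim))
        flat = draws.reshape(-1, dim)
        for block in (slice(0, p), slice(p, 2 * p)):
            mean = flat[:, block].mean(axis=0)
            mcse = flat[:, block].std(axis=0) / np.sqrt(flat.shape[0] / 20)
            assert np.all(np.abs(mean - exact_mean) < 3 * mcse + 1e-3)

    def test_prior_only_medians_near_zero(self):
        """Sampling the Cauchy prior alone (no data): per-coefficient
        medians sit at 0 (Cauchy has no mean, so medians are the target)."""
        priors = PriorSpec(coef_scale=2.5, autoscale=False)
        logpost, dim = make_log_posterior(
            np.empty((0, 2)), np.empty(0), np.empty((0, 2)), np.empty(0), priors
        )
        config = McmcConfig(chains=4, iterations=3000, thin=1, n_leapfrog=15, seed=8)
        draws, _ = hmc_sample(logpost, dim, config, init=np.zeros(dim))
        flat = draws.reshape(-1, dim)
        med = np.median(flat[:, :4], axis=0)
        # quantile MCSE for a Cauchy(0, 2.5) median at ESS ≥ a few hundred
        assert np.all(np.abs(med) < 0.6)


def _linear_cohort(slope_a, slope_b, n=150, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        age = float(rng.uniform(20, 70))
        carrier = i % 2 == 0
        mmse = 28.0 + (slope_a if carrier else slope_b) * (age - 45.0)
        rows.append(
            Participant(
                id=f"L{i}",
                age=age,
                sex="F",
                education_years=8.0,
                mmse=int(np.clip(round(mmse), 0, 30)),
                psen1_carrier=carrier,
                apoe_allele_1="e3",
                apoe_allele_2="e3",
            )
        )
    return Cohort(tuple(rows))


class TestFitGroupTrajectories:
    desk = McmcConfig(chains=2, iterations=800, thin=2, seed=3)

    def test_linear_truth_recovered(self):
        """Affine trajectories are inside the spline span: posterior mean
        curves land within 0.1 MMSE of the truth (σ fixed; exactly
        noise-free data make the free-σ posterior improper)."""
        cohort = _linear_cohort(slope_a=-0.2, slope_b=-0.05, n=240, seed=2)
        fit = fit_group_trajectories(
            cohort,
            group="psen1",
            stratum="all",
            config=McmcConfig(chains=2, iterations=1500, thin=1, seed=6),
            priors=PriorSpec(coef_scale=200.0, autoscale=False),  # ≈ flat:
            # the property under test is basis representation + centering
            sigma_fixed=1.0,
        )
        ages = np.linspace(25, 65, 50)
        curves_a, curves_b = posterior_curves(fit, ages)
        # rounding of the stored MMSE adds up-to-0.5 discretization, so
        # compare against the least-squares fit of the stored integers
        for curves, carrier in ((curves_a, True), (curves_b, False)):
            df = cohort.to_frame()
            sub = df[df.psen1_carrier == carrier]
            X = rcs_design(sub["age"].to_numpy(), fit.spec)
            beta, *_ = np.linalg.lstsq(X, sub["mmse"].to_numpy(float), rcond=None)
            target = rcs_design(ages, fit.spec) @ beta
            assert np.max(np.abs(curves.mean(axis=0) - target)) < 0.1

    def test_group_too_small_names_group(self, small_cohort):
        cohort, _ = small_cohort
        keep = [p for p in cohort if not (p.apoe_groups.e2_positive and p.psen1_carrier)][
            :260
        ]
        few = [p for p in cohort if p.apoe_groups.e2_positive and p.psen1_carrier][:3]
        reduced = Cohort(tuple(keep + few))
        with pytest.raises(ValueError, match="e2\\+"):
            fit_group_trajectories(reduced, group="e2", stratum="carriers", config=self.desk)

    def test_determinism(self, small_cohort):
        cohort, _ = small_cohort
        f1 = fit_group_trajectories(cohort, group="psen1", stratum="all", config=self.desk)
        f2 = fit_group_trajectories(cohort, group="psen1", stratum="all", config=self.desk)
        assert np.array_equal(f1.beta_a, f2.beta_a)
        assert np.array_equal(f1.sigma, f2.sigma)

    def test_draw_count_and_sigma_positive(self, small_cohort):
        cohort, _ = small_cohort
        fit = fit_group_trajectories(cohort, group="psen1", stratum="all", config=self.desk)
        expected = self.desk.chains * self.desk.n_kept_per_chain
        assert fit.n_draws == expected
        assert np.all(fit.sigma > 0)

    def test_zero_coefficients_zero_curve(self, small_cohort):
        cohort, _ = small_cohort
        fit = fit_group_trajectories(cohort, group="psen1", stratum="all", config=self.desk)
        zeroed = type(fit)(
            beta_a=np.zeros_like(fit.beta_a),
            beta_b=fit.beta_b,
            sigma=fit.sigma,
            spec=fit.spec,
            column_means=fit.column_means,
            column_scales=fit.column_scales,
            label_a=fit.label_a,
            label_b=fit.label_b,
            n_a=fit.n_a,
            n_b=fit.n_b,
            age_low=fit.age_low,
            age_high=fit.age_high,
        )
        curves_a, _ = posterior_curves(zeroed, np.linspace(25, 60, 10))
        assert np.all(curves_a == 0.0)

    def test_save_load_round_trip(self, small_cohort, tmp_path):
        cohort, _ = small_cohort
        fit = fit_group_trajectories(cohort, group="psen1", stratum="all", config=self.desk)
        path = tmp_path / "fit.npz"
        save_fit(fit, path)
        back = load_fit(path)
        assert np.array_equal(back.beta_a, fit.beta_a)
        assert back.spec == fit.spec
        assert back.label_a == fit.label_a

    def test_thinning_changes_mc_error_not_location(self):
        """Posterior medians agree across thinning/chain settings within a
        combined Monte-Carlo error allowance on a fixed cohort."""
        cohort, _ = generate_cohort(GeneratorParams(n_carriers=200, n_noncarriers=150, seed=31))
        f1 = fit_group_trajectories(
            cohort, config=McmcConfig(chains=4, iterations=1200, thin=4, seed=1)
        )
        f2 = fit_group_trajectories(
            cohort, config=McmcConfig(chains=2, iterations=1200, thin=1, seed=2)
        )
        ages = np.linspace(25, 60, 20)
        m1 = np.median(posterior_curves(f1, ages)[0], axis=0)
        m2 = np.median(posterior_curves(f2, ages)[0], axis=0)
        s1 = posterior_curves(f1, ages)[0].std(axis=0)
        tol = 3 * s1 / np.sqrt(100)  # ESS lower bound ~100 per setting
        assert np.all(np.abs(m1 - m2) < np.maximum(tol, 0.25))
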