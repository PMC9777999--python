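import math

import numpy as np
import pytest
from scipy import stats

from rbroc.binormal import (
    BinormalParams,
    SummaryStats,
    auc_binormal,
    auc_binormal_closed_form,
    cmod_inverse,
    cmod_transform,
    conditional_samples,
    copt_closed_form,
    cutoff_rb_inference,
    nonexistence_threshold,
    positivity_condition,
    prior_state,
    run_binormal_inference,
    update_conjugate,
)


def _grid_error(params, w, c):
    fnr = stats.norm.cdf((c - params.mu_d) / math.sqrt(params.sigma2_d))
    fpr = 1 - stats.norm.cdf((c - params.mu_nd) / math.sqrt(params.sigma2_nd))
    return w * fnr + (1 - w) * fpr


class TestConjugateUpdate:
    def test_zero_data_returns_prior(self, demo_normal_gamma):
        empty = SummaryStats(0, 0.0, 0.0)
        post = update_conjugate(demo_normal_gamma, empty, empty, "equal")
        pr = prior_state(demo_normal_gamma, "equal")
        assert post == pr
        post_u = update_conjugate(demo_normal_gamma, empty, empty, "unequal")
        assert post_u == prior_state(demo_normal_gamma, "unequal")

    def test_reference_equal_variance_update(self, demo_summaries,
                                             demo_normal_gamma):
        s_nd, s_d = demo_summaries
        post = update_conjugate(demo_normal_gamma, s_nd, s_d, "equal")
        # plug-in arithmetic: shape = lambda1 + 45/2, rate from the printed
        # lambda_x formula
        assert post.shape == pytest.approx(demo_normal_gamma.lambda1 + 22.5)
        lam_x = (demo_normal_gamma.lambda2 + (16.778 + 19.638) / 2
                 + (1 / 24) * (20 * 4) * 0.976**2 / 2
                 + (1 / 29) * (25 * 4) * 0.072**2 / 2)
        assert post.rate == pytest.approx(lam_x)
        assert post.nd.mean == pytest.approx((25 * -0.072) / 29)
        assert post.d.mean == pytest.approx((20 * 0.976) / 24)

    def test_posterior_mean_between_data_mean_and_prior_mean(
            self, demo_normal_gamma):
        s = SummaryStats(12, 3.0, 10.0)
        post = update_conjugate(demo_normal_gamma, s, s, "unequal")
        assert demo_normal_gamma.mu0 < post.nd.mean < s.mean

    def test_all_distinct_groups_update_separately(self, demo_summaries,
                                                   demo_normal_gamma):
        s_nd, s_d = demo_summaries
        post = update_conjugate(demo_normal_gamma, s_nd, s_d, "unequal")
        assert post.nd.shape == pytest.approx(
            demo_normal_gamma.lambda1 + 12.5)
        assert post.d.shape == pytest.approx(demo_normal_gamma.lambda1 + 10)

    def test_negative_ss_rejected(self):
        with pytest.raises(ValueError):
            SummaryStats(3, 0.0, -1.0)


class TestAUC:
    def test_reference_value(self):
        p = BinormalParams.equal_variance(0, 1, 1)
        assert auc_binormal(p) == pytest.approx(0.760, abs=5e-4)

    def test_equal_means_give_half(self):
        p = BinormalParams(2.0, 2.0, 1.5, 0.7)
        assert auc_binormal(p) == pytest.approx(0.5, abs=1e-10)

    def test_quadrature_matches_closed_form(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = BinormalParams(*rng.normal(0, 2, 2),
                               *np.exp(rng.normal(0, 0.7, 2)))
            assert auc_binormal(p) == pytest.approx(
                auc_binormal_closed_form(p), abs=1e-8)


class TestClosedFormCutoff:
    def test_reference_equal_variance_value(self):
        p = BinormalParams.equal_variance(0, 1, 1)
        r = copt_closed_form(p, 0.4)
        assert r.exists
        assert r.copt == pytest.approx(0.5 + math.log(0.6 / 0.4))
        assert r.copt == pytest.approx(0.905, abs=5e-4)

    def test_half_prevalence_gives_midpoint(self):
        p = BinormalParams.equal_variance(-1, 3, 2.0)
        assert copt_closed_form(p, 0.5).copt == pytest.approx(1.0)

    def test_wrong_mean_order_has_no_finite_cutoff(self):
        p = BinormalParams.equal_variance(1, 0, 1)
        r = copt_closed_form(p, 0.4)
        assert not r.exists and math.isinf(r.copt) and r.cmod == 1.0

    def test_unequal_variance_existence_boundary(self):
        p = BinormalParams(1, 2, 1.5**2, 1.0)
        assert not copt_closed_form(p, 0.30, "unequal").exists
        assert copt_closed_form(p, 0.31, "unequal").exists
        w_star = nonexistence_threshold(p)
        assert w_star == pytest.approx(0.30885, abs=1e-4)

    def test_unequal_limit_recovers_equal_formula(self):
        base = copt_closed_form(BinormalParams.equal_variance(0, 1, 1), 0.35)
        for delta in (1e-4, 1e-6):
            p = BinormalParams(0, 1, 1 + delta, 1.0)
            r = copt_closed_form(p, 0.35, "unequal")
            assert r.copt == pytest.approx(base.copt, abs=0.01)

    def test_grid_minimization_oracle(self):
        # whenever the closed form reports a finite cutoff whose Error
        # beats the boundary infimum min(w, 1-w), it must coincide with
        # the grid argmin; when it reports nonexistence the grid minimum
        # sits at a boundary of any finite grid
        rng = np.random.default_rng(17)
        grid = np.linspace(-25, 25, 100_001)
        checked = 0
        for _ in range(60):
            mu_nd, mu_d = np.sort(rng.normal(0, 2, 2))
            p = BinormalParams(mu_nd, mu_d, *np.exp(rng.normal(0, 0.5, 2)))
            w = rng.uniform(0.05, 0.95)
            r = copt_closed_form(p, w, "unequal")
            e = _grid_error(p, w, grid)
            if r.exists and _grid_error(p, w, r.copt) <= min(w, 1 - w):
                assert abs(grid[np.argmin(e)] - r.copt) < 1e-3
                checked += 1
            elif not r.exists:
                # no interior minimum: the error decreases toward its
                # boundary infimum min(w, 1-w), attained only in the limit
                assert e.min() >= min(w, 1 - w) - 1e-9
                assert e.min() == pytest.approx(min(w, 1 - w), abs=1e-3)
        assert checked > 20

    def test_error_limits_at_extreme_cutoffs(self):
        p = BinormalParams(0, 1, 1.2, 0.8)
        w = 0.3
        assert _grid_error(p, w, -50.0) == pytest.approx(1 - w, abs=1e-10)
        assert _grid_error(p, w, 50.0) == pytest.approx(w, abs=1e-10)

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ValueError):
            copt_closed_form(BinormalParams.equal_variance(0, 1, 1), 0.0)


class TestPositivityCondition:
    def test_equal_variances_reduce_to_mean_ordering(self):
        p = BinormalParams(0, 1, 1.0, 1.0)
        for w in (0.05, 0.5, 0.95):
            val, flag = positivity_condition(p, w)
            assert flag and val == pytest.approx(1.0)

    def test_flag_flips_at_reference_threshold(self):
        p = BinormalParams(1, 2, 1.5**2, 1.0)
        assert not positivity_condition(p, 0.30)[1]
        assert positivity_condition(p, 0.31)[1]

    def test_equivalent_to_combined_lemma_conditions(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            p = BinormalParams(*rng.normal(0, 2, 2),
                               *np.exp(rng.normal(0, 0.6, 2)))
            w = rng.uniform(0.02, 0.98)
            _, flag = positivity_condition(p, w)
            disc = (p.mu_d - p.mu_nd) ** 2 + 2 * (
                p.sigma2_d - p.sigma2_nd
            ) * math.log(((1 - w) / w) * math.sqrt(p.sigma2_d / p.sigma2_nd))
            brute = (p.mu_d >= p.mu_nd) and disc >= 0
            assert flag == brute


class TestCmod:
    def test_monotone_bijection_with_endpoints(self):
        c = np.array([-np.inf, -3.0, 0.0, 0.715, np.inf])
        v = cmod_transform(c)
        assert np.all(np.diff(v) > 0)
        assert v[0] == 0.0 and v[-1] == 1.0
        assert v[2] == 0.5
        finite = c[1:-1]
        assert np.allclose(cmod_inverse(v[1:-1]), finite)

    def test_atom_collects_infinite_cutoffs(self):
        rng = np.random.default_rng(2)
        prior = np.concatenate([rng.uniform(0.2, 0.8, 900),
                                np.ones(100)])  # 10% nonexistent
        post = rng.uniform(0.4, 0.6, 1000)
        inf = cutoff_rb_inference(prior, post, L=10)
        assert inf.atom_prior == pytest.approx(0.1)
        assert inf.atom_posterior == 0.0


class TestConditionalSampling:
    def test_symmetric_prior_orders_means_half_the_time(self,
                                                        demo_normal_gamma):
        rng = np.random.default_rng(31)
        st_prior = prior_state(demo_normal_gamma, "equal")
        N = 50_000
        s2 = 1 / rng.gamma(st_prior.shape, 1 / st_prior.rate, N)
        mu_d = rng.normal(0, 0.5 * np.sqrt(s2))
        mu_nd = rng.normal(0, 0.5 * np.sqrt(s2))
        frac = (mu_d > mu_nd).mean()
        assert frac == pytest.approx(0.5, abs=3 * math.sqrt(0.25 / N))

    def test_importance_sampler_matches_rejection_oracle(
            self, demo_summaries, demo_normal_gamma):
        s_nd, s_d = demo_summaries
        post = update_conjugate(demo_normal_gamma, s_nd, s_d, "equal")
        rng = np.random.default_rng(5)
        cond = conditional_samples(post, "muD_gt_muND", 100_000, rng)
        gap_w = float(np.sum((cond.mu_d - cond.mu_nd) * cond.weights))

        # rejection oracle on the same posterior
        s2 = 1 / rng.gamma(post.shape, 1 / post.rate, 200_000)
        s = np.sqrt(s2)
        mu_d = rng.normal(post.d.mean, np.sqrt(post.d.kappa) * s)
        mu_nd = rng.normal(post.nd.mean, np.sqrt(post.nd.kappa) * s)
        keep = mu_d > mu_nd
        gap_r = (mu_d[keep] - mu_nd[keep]).mean()
        se = (mu_d[keep] - mu_nd[keep]).std() / math.sqrt(keep.sum())
        assert gap_w == pytest.approx(gap_r, abs=4 * se)
        assert cond.ess > 0.5 * 100_000

    def test_truncation_respected(self, demo_summaries, demo_normal_gamma):
        s_nd, s_d = demo_summaries
        post = update_conjugate(demo_normal_gamma, s_nd, s_d, "equal")
        cond = conditional_samples(post, "muD_gt_muND", 10_000,
                                   np.random.default_rng(0))
        assert np.all(cond.mu_nd <= cond.mu_d)

    def test_rejection_event_requires_prevalence(self, demo_summaries,
                                                 demo_normal_gamma):
        s_nd, s_d = demo_summaries
        post = update_conjugate(demo_normal_gamma, s_nd, s_d, "unequal")
        with pytest.raises(ValueError, match="w_draws"):
            conditional_samples(post, "eq8", 1000, np.random.default_rng(0))


@pytest.fixture(scope="module")
def report(demo_summaries, demo_normal_gamma, demo_prevalence_prior):
    s_nd, s_d = demo_summaries
    return run_binormal_inference(
        s_nd, s_d, demo_normal_gamma, prevalence=demo_prevalence_prior,
        variant="equal", scheme="ii", N=100_000, seed=11,
    )


class TestRunInference:
    def test_h0_assessment_uses_analytic_prior_half(self, report):
        assert report.h0.prior_prob == 0.5
        assert report.h0.prior_prob_analytic
        assert report.h0.rb == pytest.approx(2.0, abs=0.01)
        assert report.h0.rb <= 2.0
        assert report.h0.strength > 0.99

    def test_auc_estimate_near_reference(self, report):
        assert report.auc.estimate == pytest.approx(0.795, abs=0.05)
        lo, hi = report.auc.plausible_region
        assert lo == pytest.approx(0.67, abs=0.06)
        assert hi == pytest.approx(0.88, abs=0.06)
        assert 0.75 <= report.auc.plausible_content <= 0.92

    def test_cutoff_estimate_near_reference(self, report):
        assert report.cutoff.estimate == pytest.approx(0.715, abs=0.12)
        lo, hi = report.cutoff.plausible_interval
        assert lo == pytest.approx(0.316, abs=0.15)
        assert hi == pytest.approx(1.228, abs=0.15)
        assert report.cutoff.atom_posterior == 0.0

    def test_prevalence_inference_exact(self, report):
        p = report.prevalence
        assert p.estimate == pytest.approx(0.444, abs=5e-4)
        assert p.plausible_interval[0] == pytest.approx(0.374, abs=2e-3)
        assert p.plausible_interval[1] == pytest.approx(0.516, abs=2e-3)
        assert p.plausible_content == pytest.approx(0.782, abs=2e-3)

    def test_error_characteristics_near_reference(self, report):
        est = {k: v.estimate for k, v in report.error_characteristics.items()}
        assert est["fnr"] == pytest.approx(0.41, abs=0.08)
        assert est["fpr"] == pytest.approx(0.22, abs=0.08)
        assert est["error"] == pytest.approx(0.27, abs=0.08)

    def test_unequal_variant_similar_auc(self, demo_summaries,
                                         demo_normal_gamma,
                                         demo_prevalence_prior):
        s_nd, s_d = demo_summaries
        rep = run_binormal_inference(
            s_nd, s_d, demo_normal_gamma, prevalence=demo_prevalence_prior,
            variant="unequal", scheme="ii", N=50_000, seed=7,
        )
        assert rep.h0.direction == "favor"
        assert rep.auc.estimate == pytest.approx(0.79, abs=0.06)

    def test_cmod_inference_matches_direct_grid_inference(
            self, demo_summaries, demo_normal_gamma):
        # reparameterization invariance: RB inference on the cmod scale,
        # back-transformed, equals RB inference done directly on a matched
        # cutoff grid
        s_nd, s_d = demo_summaries
        rng = np.random.default_rng(19)
        post = update_conjugate(demo_normal_gamma, s_nd, s_d, "equal")
        pr = prior_state(demo_normal_gamma, "equal")
        c_prior = conditional_samples(pr, "muD_gt_muND", 50_000, rng)
        c_post = conditional_samples(post, "muD_gt_muND", 50_000, rng)
        w = 0.4

        def copts(c):
            return ((c.mu_d + c.mu_nd) / 2
                    + c.sigma2_d / (c.mu_d - c.mu_nd) * math.log(0.6 / 0.4))

        L = 20
        inf = cutoff_rb_inference(
            cmod_transform(copts(c_prior)), cmod_transform(copts(c_post)),
            L=L, prior_weights=c_prior.weights,
            posterior_weights=c_post.weights,
        )
        # direct histogram on the matched (tan-warped) cutoff grid
        edges = cmod_inverse(np.linspace(0, 1, L + 1))
        hp = np.histogram(copts(c_prior), bins=edges,
                          weights=c_prior.weights)[0]
        hq = np.histogram(copts(c_post), bins=edges,
                          weights=c_post.weights)[0]
        rb = np.where(hp > 0, hq / np.maximum(hp, 1e-300), -1)
        assert int(np.argmax(rb)) == int(
            np.argmax(np.where(np.isfinite(inf.rb), inf.rb, -1)))

    def test_same_seed_reproduces(self, demo_summaries, demo_normal_gamma):
        s_nd, s_d = demo_summaries
        kw = dict(prevalence=0.4, variant="equal", scheme="i", N=5000, seed=2)
        a = run_binormal_inference(s_nd, s_d, demo_normal_gamma, **kw)
        b = run_binormal_inference(s_nd, s_d, demo_normal_gamma, **kw)
        assert np.array_equal(a.auc.posterior.masses, b.auc.posterior.masses)
        assert a.cutoff.estimate == b.cutoff.estimate
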