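import math

import numpy as np
import pytest

from rbroc import fixtures
from rbroc.dp import (
    DPPriorSpec,
    FiniteDPApprox,
    functionals_from_processes,
    run_dp_inference,
    sample_posterior_process,
    sample_prior_process,
    update_base_posterior,
)
from rbroc.elicitation import NormalGammaParams, elicit_beta_prevalence


@pytest.fixture(scope="module")
def base():
    return NormalGammaParams(mu0=0.0, tau0=0.5, lambda1=1.787, lambda2=1.056)


class TestPriorProcess:
    def test_weights_sum_to_one(self, base):
        spec = DPPriorSpec(a=10, base=base, nstar=200)
        rng = np.random.default_rng(0)
        for _ in range(5):
            f, _ = sample_prior_process(spec, rng)
            assert f.weights.sum() == pytest.approx(1.0)

    def test_dp_moment_identities(self, base):
        # for fixed base parameters: E F(A) = H(A) and
        # Var F(A) = H(A)(1-H(A))/(1+a)
        a, mu, s2 = 8.0, 0.3, 1.4
        spec = DPPriorSpec(a=a, base=base, nstar=1000)
        rng = np.random.default_rng(1)
        lo, hi = -0.5, 1.2
        from scipy import stats
        h = (stats.norm.cdf(hi, mu, math.sqrt(s2))
             - stats.norm.cdf(lo, mu, math.sqrt(s2)))
        vals = []
        n_rep = 1500
        for _ in range(n_rep):
            weights = rng.dirichlet(np.full(spec.nstar, a / spec.nstar))
            atoms = rng.normal(mu, math.sqrt(s2), spec.nstar)
            vals.append(weights[(atoms > lo) & (atoms <= hi)].sum())
        vals = np.asarray(vals)
        target_var = h * (1 - h) / (1 + a)
        assert vals.mean() == pytest.approx(
            h, abs=3 * math.sqrt(target_var / n_rep))
        assert vals.var() == pytest.approx(target_var, rel=0.15)


class TestBasePosterior:
    def test_empty_data_returns_prior(self, base):
        post, summ = update_base_posterior(base, [])
        assert (post.mean, post.kappa) == (base.mu0, base.tau0**2)
        assert (post.shape, post.rate) == (base.lambda1, base.lambda2)
        assert summ.n_unique == 0

    def test_unique_value_summaries(self, base):
        _, summ = update_base_posterior(base, [1.0, 1.0, 2.0])
        assert summ.n_unique == 2
        assert summ.unique_mean == pytest.approx(1.5)
        assert summ.unique_ss == pytest.approx(0.5)

    def test_all_distinct_matches_standard_conjugate_update(self, base):
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 1.0, 15)
        post, summ = update_base_posterior(base, x)
        assert summ.n_unique == 15
        inv_t2 = 1 / base.tau0**2
        kappa = 1 / (15 + inv_t2)
        assert post.mean == pytest.approx(kappa * (15 * x.mean()))
        assert post.shape == pytest.approx(base.lambda1 + 7.5)


class TestPosteriorProcess:
    def test_no_data_reduces_to_prior_process(self, base):
        spec = DPPriorSpec(a=5, base=base, nstar=100, nstarstar=100)
        f = sample_posterior_process(spec, (0.0, 1.0), [],
                                     np.random.default_rng(0))
        assert f.weights.sum() == pytest.approx(1.0)
        assert np.unique(f.atoms).size == 100  # all from the continuous base

    def test_ecdf_resampling_fraction(self, base):
        data = np.arange(40.0) * 1000  # far from the base, identifiable
        a = 10.0
        spec = DPPriorSpec(a=a, base=base, nstar=100, nstarstar=2000)
        f = sample_posterior_process(spec, (0.0, 1.0), data,
                                     np.random.default_rng(7))
        frac = np.isin(f.atoms, data).mean()
        expect = data.size / (a + data.size)
        assert frac == pytest.approx(
            expect, abs=3 * math.sqrt(expect * (1 - expect) / 2000))

    def test_large_concentration_ignores_data(self, base):
        data = np.arange(10.0) * 1000
        spec = DPPriorSpec(a=1e7, base=base, nstar=100, nstarstar=500)
        f = sample_posterior_process(spec, (0.0, 1.0), data,
                                     np.random.default_rng(2))
        assert np.isin(f.atoms, data).mean() < 0.01


class TestFunctionals:
    def test_identical_processes_fall_below_half_by_ties(self):
        rng = np.random.default_rng(4)
        atoms = rng.normal(0, 1, 50)
        weights = rng.dirichlet(np.ones(50))
        f = FiniteDPApprox(atoms, weights)
        res = functionals_from_processes(f, FiniteDPApprox(atoms, weights),
                                         0.5)
        expect = float(np.sum((1 - f.cdf(f.atoms)) * f.weights))
        assert res.auc == pytest.approx(expect)
        assert res.auc < 0.5

    def test_auc_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            f_nd = FiniteDPApprox(rng.normal(0, 1, k), rng.dirichlet(np.ones(k)))
            f_d = FiniteDPApprox(rng.normal(1, 1, k), rng.dirichlet(np.ones(k)))
            brute = sum(
                pw * qw
                for c_nd, pw in zip(f_nd.atoms, f_nd.weights)
                for c_d, qw in zip(f_d.atoms, f_d.weights)
                if c_d > c_nd
            )
            res = functionals_from_processes(f_nd, f_d, 0.3)
            assert res.auc == pytest.approx(brute)
            assert 0.0 <= res.auc <= 1.0

    def test_dominating_degenerate_process_has_auc_one(self):
        f_nd = FiniteDPApprox([0.0, 1.0, 2.0], [0.3, 0.4, 0.3])
        f_d = FiniteDPApprox([10.0], [1.0])
        assert functionals_from_processes(f_nd, f_d, 0.5).auc == 1.0

    def test_copt_minimizes_error_over_atom_union(self):
        rng = np.random.default_rng(6)
        f_nd = FiniteDPApprox(rng.normal(0, 1, 30), rng.dirichlet(np.ones(30)))
        f_d = FiniteDPApprox(rng.normal(2, 1, 30), rng.dirichlet(np.ones(30)))
        res = functionals_from_processes(f_nd, f_d, 0.4)
        assert res.copt == res.candidates[np.argmin(res.error)]
        # ties broken to the smallest candidate
        first_min = res.candidates[
            np.flatnonzero(res.error == res.error.min()).min()]
        assert res.copt == first_min


@pytest.fixture(scope="module")
def report():
    x_nd, x_d = fixtures.demo_binormal_dataset(0)
    base = NormalGammaParams(0.0, 0.5, 1.787, 1.056)
    spec = DPPriorSpec(a=20.0, base=base, nstar=300, nstarstar=300)
    prev = elicit_beta_prevalence(0.2, 0.6, 0.99)
    return run_dp_inference(x_nd, x_d, spec, prevalence=prev,
                            scheme="ii", N=1200, seed=5)


class TestRunInference:
    def test_h0_relative_belief_near_its_maximum(self, report):
        # the prior probability of AUC > 1/2 is essentially 1/2, so strong
        # posterior evidence drives RB toward its maximum of about 2
        assert report.h0.direction == "favor"
        assert report.h0.rb == pytest.approx(1.992, abs=0.12)
        assert report.h0.strength > 0.98

    def test_conditioned_auc_estimate_reasonable(self, report):
        assert report.conditioned
        assert report.auc.estimate == pytest.approx(0.839, abs=0.08)
        lo, hi = report.auc.plausible_region
        assert 0.6 <= lo <= 0.78 and 0.86 <= hi <= 1.0

    def test_cutoff_interval_covers_reference(self, report):
        lo, hi = report.cutoff.plausible_interval
        assert lo < 0.905 < hi  # the generating model's optimal cutoff
        assert 0.5 <= report.cutoff.plausible_content <= 1.0

    def test_error_characteristics_present_and_bounded(self, report):
        assert set(report.error_characteristics) == {
            "fnr", "fpr", "error", "fdr", "fndr"}
        for r in report.error_characteristics.values():
            assert 0.0 <= r.estimate <= 1.0

    def test_posterior_concentrates_toward_binormal_auc_for_large_a(self):
        # with a huge concentration the DP posterior pins the base normal,
        # so the AUC distribution concentrates near the binormal value
        x_nd, x_d, _, _ = fixtures.generate_binormal_dataset(
            fixtures.BinormalParams.equal_variance(0, 1.5, 1), 60, 60, 11)
        base = NormalGammaParams(0.0, 0.5, 1.787, 1.056)
        spec = DPPriorSpec(a=5000.0, base=base, nstar=400, nstarstar=400)
        rep = run_dp_inference(x_nd, x_d, spec, prevalence=0.4,
                               N=600, seed=3, condition=False)
        from rbroc.binormal import auc_binormal_closed_form, BinormalParams
        target = auc_binormal_closed_form(
            BinormalParams.equal_variance(0, 1.5, 1))
        assert rep.auc.estimate == pytest.approx(target, abs=0.1)

    def test_same_seed_reproduces(self):
        x_nd, x_d = fixtures.demo_binormal_dataset(0)
        base = NormalGammaParams(0.0, 0.5, 1.787, 1.056)
        spec = DPPriorSpec(a=20.0, base=base, nstar=100, nstarstar=100)
        kw = dict(prevalence=0.4, N=200, seed=8)
        a = run_dp_inference(x_nd, x_d, spec, **kw)
        b = run_dp_inference(x_nd, x_d, spec, **kw)
        assert np.array_equal(a.auc.posterior.masses, b.auc.posterior.masses)
        assert a.cutoff.estimate == b.cutoff.estimate
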