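"""Nonparametric model: mixture-Dirichlet-process priors on the two group
distributions.

Each group distribution gets a ``DP(a, N(mu, sigma^2))`` prior whose base
parameters carry a normal-gamma hyperprior, so the model allows arbitrary
departures from normality while centering beliefs on a normal shape; the
concentration ``a`` encodes how strongly normality is believed (elicited
from a discrepancy bound, see :mod:`rbroc.elicitation`).

Process draws use the finite Dirichlet-weights approximation: ``n*`` atoms
drawn iid from the base with ``Dirichlet(a/n*, ..., a/n*)`` weights, which
converges weakly to the DP as ``n*`` grows.  A posteriori, the base
parameters are updated from the *unique* observed values (the DP makes
ties informative about the base only once) and atoms are drawn from the
predictive mixture ``a/(a+n) * base + n/(a+n) * ecdf`` with
``Dirichlet((a+n)/n**, ...)`` weights.

The AUC, the error-minimizing cutoff over the union of atom supports, and
the error characteristics are evaluated per process draw, and relative
belief inference proceeds exactly as in the parametric models; the cutoff
posterior on the cmod scale is smoothed with a short moving average
because resampling the ecdf atoms makes it highly multimodal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .binormal import (
    CutoffInference,
    RateInference,
    cutoff_rb_inference,
    cmod_transform,
    rate_rb,
)
from .elicitation import NormalGammaParams, PrevalencePrior
from . import rb_core
from .rb_core import (
    DEFAULT_L,
    EvidenceAssessment,
    RelativeBeliefSummary,
    assess_event,
    beta_binomial_rb,
    discretize,
    relative_belief,
)

__all__ = [
    "DPPriorSpec",
    "FiniteDPApprox",
    "UniqueDataSummary",
    "BasePosterior",
    "DPReport",
    "sample_prior_process",
    "update_base_posterior",
    "sample_posterior_process",
    "functionals_from_processes",
    "run_dp_inference",
]


@dataclass(frozen=True)
class DPPriorSpec:
    """Concentration, base hyperprior and approximation sizes."""

    a: float
    base: NormalGammaParams
    nstar: int = 1000
    nstarstar: int = 1000

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("concentration must be positive")
        if self.nstar < 10 or self.nstarstar < 10:
            raise ValueError("approximation sizes must be at least 10")


@dataclass
class FiniteDPApprox:
    """Finite approximation of a DP draw: weighted atoms, evaluated as a
    right-continuous step cdf."""

    atoms: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.atoms.shape != self.weights.shape:
            raise ValueError("atoms and weights must align")
        if not math.isclose(self.weights.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")
        order = np.argsort(self.atoms, kind="stable")
        self.atoms = self.atoms[order]
        self.weights = self.weights[order]
        self._cum = np.cumsum(self.weights)

    def cdf(self, x) -> np.ndarray:
        """P(X <= x), right-continuous."""
        idx = np.searchsorted(self.atoms, np.asarray(x, dtype=float),
                              side="right")
        out = np.where(idx > 0, self._cum[np.maximum(idx - 1, 0)], 0.0)
        return out


def sample_prior_process(
    spec: DPPriorSpec, rng: np.random.Generator
) -> tuple[FiniteDPApprox, tuple[float, float]]:
    """One draw from the prior: base parameters from the normal-gamma
    hyperprior, atoms iid from the base normal, Dirichlet(a/n*) weights."""
    mu, s2 = spec.base.sample_base(1, rng)
    mu, s2 = float(mu[0]), float(s2[0])
    weights = rng.dirichlet(np.full(spec.nstar, spec.a / spec.nstar))
    atoms = rng.normal(mu, math.sqrt(s2), spec.nstar)
    return FiniteDPApprox(atoms, weights), (mu, s2)


@dataclass(frozen=True)
class UniqueDataSummary:
    """Unique-value summaries driving the base posterior, plus the ecdf
    support of the full sample."""

    n: int
    n_unique: int
    unique_mean: float
    unique_ss: float
    data: np.ndarray  # full sample (ecdf support)


@dataclass(frozen=True)
class BasePosterior:
    """Posterior normal-gamma state of one group's base parameters:
    ``mu | sigma^2 ~ N(mean, kappa sigma^2)``, ``1/sigma^2 ~ gamma(shape,
    rate)``."""

    mean: float
    kappa: float
    shape: float
    rate: float

    def sample(self, n: int, rng: np.random.Generator):
        inv = rng.gamma(self.shape, 1.0 / self.rate, n)
        s2 = 1.0 / inv
        mu = rng.normal(self.mean, np.sqrt(self.kappa * s2))
        return mu, s2


def update_base_posterior(
    prior: NormalGammaParams, data
) -> tuple[BasePosterior, UniqueDataSummary]:
    """Normal-gamma update of the base parameters from unique values only.

    Under the DP the posterior density of ``(mu, sigma^2)`` involves each
    distinct observed value once, so the update uses the count, mean and
    sum of squared deviations of the unique values.  Empty data returns
    the prior state.
    """
    x = np.asarray(data, dtype=float).ravel()
    uniq = np.unique(x)
    nt = uniq.size
    if nt == 0:
        summary = UniqueDataSummary(0, 0, math.nan, 0.0, x)
        return BasePosterior(prior.mu0, prior.tau0**2, prior.lambda1,
                             prior.lambda2), summary
    xbar = float(uniq.mean())
    ss = float(np.sum((uniq - xbar) ** 2))
    inv_t2 = 1.0 / prior.tau0**2
    kappa = 1.0 / (nt + inv_t2)
    mean = kappa * (nt * xbar + prior.mu0 * inv_t2)
    rate = (prior.lambda2 + ss / 2.0
            + kappa * (nt * inv_t2) * (xbar - prior.mu0) ** 2 / 2.0)
    post = BasePosterior(mean, kappa, prior.lambda1 + nt / 2.0, rate)
    return post, UniqueDataSummary(x.size, nt, xbar, ss, x)


def sample_posterior_process(
    spec: DPPriorSpec,
    base_draw: tuple[float, float],
    data,
    rng: np.random.Generator,
) -> FiniteDPApprox:
    """One draw from the posterior process given base parameters.

    Atoms come from the predictive mixture: with probability ``a/(a+n)``
    from the base normal, otherwise resampled from the data (ecdf);
    weights are ``Dirichlet((a+n)/n**, ...)``.  With no data this reduces
    to the prior process.
    """
    x = np.asarray(data, dtype=float).ravel()
    n = x.size
    mu, s2 = base_draw
    m = spec.nstarstar
    weights = rng.dirichlet(np.full(m, (spec.a + n) / m))
    if n == 0:
        atoms = rng.normal(mu, math.sqrt(s2), m)
    else:
        from_base = rng.random(m) < spec.a / (spec.a + n)
        atoms = np.where(from_base,
                         rng.normal(mu, math.sqrt(s2), m),
                         rng.choice(x, m))
    return FiniteDPApprox(atoms, weights)


@dataclass
class ProcessFunctionals:
    auc: float
    candidates: np.ndarray
    fnr: np.ndarray
    fpr: np.ndarray
    error: np.ndarray
    copt: float
    copt_index: int


def functionals_from_processes(
    f_nd: FiniteDPApprox, f_d: FiniteDPApprox, w: float
) -> ProcessFunctionals:
    """AUC, per-candidate rates and the Error-minimizing cutoff of a pair
    of process draws.

    ``AUC = sum_i (1 - F_D(c_NDi)) p_NDi`` (ties contribute zero); the
    candidate cutoffs are the sorted union of both atom sets, on which the
    piecewise-constant Error is minimized (ties to the smallest cutoff).
    """
    auc = float(np.sum((1.0 - f_d.cdf(f_nd.atoms)) * f_nd.weights))
    candidates = np.union1d(f_nd.atoms, f_d.atoms)
    fnr = f_d.cdf(candidates)
    fpr = 1.0 - f_nd.cdf(candidates)
    err = w * fnr + (1.0 - w) * fpr
    idx = int(np.argmin(err))
    return ProcessFunctionals(auc, candidates, fnr, fpr, err,
                              float(candidates[idx]), idx)


def _auc_and_copt_arrays(f_nd, f_d, w):
    """Fast path used inside the Monte Carlo loop."""
    auc = float(np.sum((1.0 - f_d.cdf(f_nd.atoms)) * f_nd.weights))
    candidates = np.concatenate([f_nd.atoms, f_d.atoms])
    candidates.sort(kind="stable")
    fnr = f_d.cdf(candidates)
    fpr = 1.0 - f_nd.cdf(candidates)
    err = w * fnr + (1.0 - w) * fpr
    return auc, float(candidates[int(np.argmin(err))])


@dataclass
class DPReport:
    h0: EvidenceAssessment
    conditioned: bool
    auc: RelativeBeliefSummary
    cutoff: CutoffInference
    error_characteristics: dict[str, RateInference]
    prevalence: rb_core.BetaPrevalenceInference | None
    prevalence_mode: str
    acceptance_prior: float
    acceptance_posterior: float
    settings: dict


def _prior_loop(spec, w_draws, rng, n_draws):
    auc = np.empty(n_draws)
    copt = np.empty(n_draws)
    for i in range(n_draws):
        f_nd, _ = sample_prior_process(spec, rng)
        f_d, _ = sample_prior_process(spec, rng)
        auc[i], copt[i] = _auc_and_copt_arrays(f_nd, f_d, w_draws[i])
    return auc, copt


def _posterior_loop(spec, post_nd, post_d, x_nd, x_d, w_draws, rng, n_draws):
    auc = np.empty(n_draws)
    copt = np.empty(n_draws)
    for i in range(n_draws):
        b_nd = post_nd.sample(1, rng)
        b_d = post_d.sample(1, rng)
        f_nd = sample_posterior_process(spec, (b_nd[0][0], b_nd[1][0]),
                                        x_nd, rng)
        f_d = sample_posterior_process(spec, (b_d[0][0], b_d[1][0]),
                                       x_d, rng)
        auc[i], copt[i] = _auc_and_copt_arrays(f_nd, f_d, w_draws[i])
    return auc, copt


def _rates_loop(sampler, c_hat, n_draws):
    out = {k: np.empty(n_draws) for k in
           ("auc", "fnr", "fpr", "error", "fdr", "fndr")}
    for i in range(n_draws):
        f_nd, f_d, w = sampler()
        fnr = float(f_d.cdf(c_hat))
        fpr = 1.0 - float(f_nd.cdf(c_hat))
        den_pos = w * (1 - fnr) + (1 - w) * fpr
        den_neg = w * fnr + (1 - w) * (1 - fpr)
        out["auc"][i] = float(np.sum((1.0 - f_d.cdf(f_nd.atoms))
                                     * f_nd.weights))
        out["fnr"][i] = fnr
        out["fpr"][i] = fpr
        out["error"][i] = w * fnr + (1 - w) * fpr
        out["fdr"][i] = (1 - w) * fpr / den_pos if den_pos > 0 else math.nan
        out["fndr"][i] = w * fnr / den_neg if den_neg > 0 else math.nan
    return out


def run_dp_inference(
    x_nd,
    x_d,
    spec: DPPriorSpec,
    prevalence: float | PrevalencePrior,
    scheme: str = "ii",
    N: int = 5000,
    L: int = DEFAULT_L,
    cmod_L: int | None = None,
    seed: int = 0,
    condition: bool = True,
    smooth_window: int = 3,
    jitter: bool = False,
    acceptance_floor: float = 1e-3,
) -> DPReport:
    """Full relative-belief ROC analysis under the mixture-DP model.

    ``N`` process pairs are drawn from the prior and from the posterior;
    the usual sequence follows (assess ``AUC > 1/2``, condition by
    rejection, RB inference for AUC and for the cutoff on the smoothed
    cmod scale).  The error characteristics at the fixed estimated cutoff
    come from a second simulation with its own child seed, as the cutoff
    estimate must be fixed before those profiles are meaningful.

    ``jitter`` adds Uniform(0,1) noise to the observations (an explicit
    opt-in for heavily tied integer-valued data; never automatic).
    """
    if scheme not in ("i", "ii"):
        raise ValueError("scheme must be 'i' or 'ii'")
    cmod_L = L if cmod_L is None else cmod_L
    rng = np.random.default_rng(seed)
    x_nd = np.asarray(x_nd, dtype=float).ravel()
    x_d = np.asarray(x_d, dtype=float).ravel()
    if jitter:
        x_nd = x_nd + rng.uniform(0, 1, x_nd.size)
        x_d = x_d + rng.uniform(0, 1, x_d.size)

    post_nd, _ = update_base_posterior(spec.base, x_nd)
    post_d, _ = update_base_posterior(spec.base, x_d)

    if isinstance(prevalence, PrevalencePrior):
        w_prior = prevalence.sample(N, rng)
        if scheme == "ii" and not prevalence.degenerate:
            b1, b2 = prevalence.updated(x_d.size, x_nd.size)
            w_post = rng.beta(b1, b2, N)
            prev_inf = beta_binomial_rb(prevalence.alpha1, prevalence.alpha2,
                                        x_d.size, x_nd.size)
            prev_mode = "posterior"
        else:
            w_post = prevalence.sample(N, rng)
            prev_inf, prev_mode = None, "prior-only"
    else:
        wv = float(prevalence)
        w_prior = np.full(N, wv)
        w_post = np.full(N, wv)
        prev_inf, prev_mode = None, "known"

    auc_prior, copt_prior = _prior_loop(spec, w_prior, rng, N)
    auc_post, copt_post = _posterior_loop(spec, post_nd, post_d, x_nd, x_d,
                                          w_post, rng, N)
    h0 = assess_event(auc_prior > 0.5, auc_post > 0.5)

    do_condition = condition and h0.direction == "favor"
    if do_condition:
        keep_prior = auc_prior > 0.5
        keep_post = auc_post > 0.5
        acc_prior = float(keep_prior.mean())
        acc_post = float(keep_post.mean())
        if min(acc_prior, acc_post) < acceptance_floor:
            raise RuntimeError("rejection acceptance rate below floor")
    else:
        keep_prior = np.ones(N, dtype=bool)
        keep_post = np.ones(N, dtype=bool)
        acc_prior = acc_post = 1.0

    auc_summary = relative_belief(
        discretize(np.clip(auc_prior[keep_prior], 0, 1), L=L),
        discretize(np.clip(auc_post[keep_post], 0, 1), L=L),
    )
    cutoff = cutoff_rb_inference(
        cmod_transform(copt_prior[keep_prior]),
        cmod_transform(copt_post[keep_post]),
        L=cmod_L,
        smooth_window=smooth_window,
    )

    # second simulation with the estimated cutoff fixed
    c_hat = cutoff.estimate
    characteristics: dict[str, RateInference] = {}
    if math.isfinite(c_hat):
        child = rng.spawn(2)

        def prior_sampler(rg=child[0], it=iter(range(N))):
            i = next(it)
            f_nd, _ = sample_prior_process(spec, rg)
            f_d, _ = sample_prior_process(spec, rg)
            return f_nd, f_d, w_prior[i]

        def post_sampler(rg=child[1], it=iter(range(N))):
            i = next(it)
            b_nd = post_nd.sample(1, rg)
            b_d = post_d.sample(1, rg)
            f_nd = sample_posterior_process(spec, (b_nd[0][0], b_nd[1][0]),
                                            x_nd, rg)
            f_d = sample_posterior_process(spec, (b_d[0][0], b_d[1][0]),
                                           x_d, rg)
            return f_nd, f_d, w_post[i]

        r_prior = _rates_loop(prior_sampler, c_hat, N)
        r_post = _rates_loop(post_sampler, c_hat, N)
        kp = r_prior.pop("auc") > 0.5 if do_condition else np.ones(N, bool)
        kq = r_post.pop("auc") > 0.5 if do_condition else np.ones(N, bool)
        if not do_condition:
            r_prior.pop("auc")
            r_post.pop("auc")
        for name in r_prior:
            characteristics[name] = rate_rb(r_prior[name][kp],
                                            r_post[name][kq], L)

    return DPReport(
        h0=h0,
        conditioned=do_condition,
        auc=auc_summary,
        cutoff=cutoff,
        error_characteristics=characteristics,
        prevalence=prev_inf if scheme == "ii" else None,
        prevalence_mode=prev_mode,
        acceptance_prior=acc_prior,
        acceptance_posterior=acc_post,
        settings={"N": N, "L": L, "cmod_L": cmod_L, "seed": seed,
                  "a": spec.a, "nstar": spec.nstar,
                  "nstarstar": spec.nstarstar, "scheme": scheme,
                  "smooth_window": smooth_window, "jitter": jitter},
    )
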