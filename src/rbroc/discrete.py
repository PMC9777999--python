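"""Ordered-discrete diagnostic model.

The diagnostic ``X`` takes values on a finite ordered scale
``c_1 < ... < c_m`` with category probabilities ``p_ND`` and ``p_D`` in the
nondiseased and diseased groups.  Independent Dirichlet priors on the two
probability vectors are conjugate to the multinomial counts, and every
quantity of interest — the AUC, the error-minimizing cutoff and the error
characteristics at that cutoff — is a function of ``(p_ND, p_D)`` and the
prevalence ``w``, so prior and posterior Monte Carlo samples of the
probability vectors induce prior and posterior distributions for all of
them.

The AUC here is ``sum_i (1 - F_D(c_i)) p_NDi``, the probability that a
diseased subject scores *strictly* higher than a nondiseased one (ties
contribute nothing).  The inferential sequence follows the relative-belief
methodology: assess ``H0: AUC > 1/2`` first; if the evidence favors it,
condition both prior and posterior on that event (by rejection) before
estimating the AUC, the cutoff and the error profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .elicitation import PrevalencePrior
from .errors import ErrorProfile, error_profile
from . import rb_core
from .rb_core import (
    DEFAULT_L,
    DEFAULT_N,
    EvidenceAssessment,
    FiniteSupportRB,
    GridDensity,
    RelativeBeliefSummary,
    assess_event,
    beta_binomial_rb,
    discretize,
    finite_relative_belief,
    relative_belief,
)

__all__ = [
    "CategoryScale",
    "DirichletSpec",
    "ProbPair",
    "RatesTable",
    "DiscreteReport",
    "auc_discrete",
    "rates_and_copt",
    "posterior_dirichlet",
    "monotone_from_simplex",
    "sample_monotone_probabilities",
    "run_discrete_inference",
]


@dataclass(frozen=True)
class CategoryScale:
    """Ordered measurement scale ``c_1 < ... < c_m``."""

    cutpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cutpoints) < 2:
            raise ValueError("need at least 2 categories")
        if not all(a < b for a, b in zip(self.cutpoints, self.cutpoints[1:])):
            raise ValueError("cutpoints must be strictly increasing")

    @property
    def m(self) -> int:
        return len(self.cutpoints)

    @classmethod
    def integer(cls, m: int) -> "CategoryScale":
        return cls(tuple(float(i) for i in range(1, m + 1)))


@dataclass
class ProbPair:
    """Category probability vectors for the two groups."""

    p_nd: np.ndarray
    p_d: np.ndarray

    def __post_init__(self) -> None:
        self.p_nd = np.asarray(self.p_nd, dtype=float)
        self.p_d = np.asarray(self.p_d, dtype=float)
        for name, p in (("p_nd", self.p_nd), ("p_d", self.p_d)):
            if p.ndim != 1 or p.size < 2:
                raise ValueError(f"{name} must be a vector of length >= 2")
            if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-12):
                raise ValueError(f"{name} must be a probability vector")
        if self.p_nd.size != self.p_d.size:
            raise ValueError("probability vectors must have equal length")

    @property
    def m(self) -> int:
        return self.p_nd.size


@dataclass
class DirichletSpec:
    """Dirichlet concentrations and observed counts for the two groups."""

    alpha_nd: np.ndarray
    alpha_d: np.ndarray
    f_nd: np.ndarray
    f_d: np.ndarray

    def __post_init__(self) -> None:
        self.alpha_nd = np.asarray(self.alpha_nd, dtype=float)
        self.alpha_d = np.asarray(self.alpha_d, dtype=float)
        self.f_nd = np.asarray(self.f_nd)
        self.f_d = np.asarray(self.f_d)
        m = self.alpha_nd.size
        if not (self.alpha_d.size == self.f_nd.size == self.f_d.size == m):
            raise ValueError("all vectors must share the scale length m")
        if np.any(self.alpha_nd <= 0) or np.any(self.alpha_d <= 0):
            raise ValueError("Dirichlet concentrations must be positive")
        if np.any(self.f_nd < 0) or np.any(self.f_d < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def m(self) -> int:
        return self.alpha_nd.size

    @classmethod
    def uniform(cls, f_nd, f_d) -> "DirichletSpec":
        f_nd = np.asarray(f_nd)
        return cls(np.ones(f_nd.size), np.ones(f_nd.size), f_nd, f_d)


def posterior_dirichlet(spec: DirichletSpec) -> DirichletSpec:
    """Conjugate update: posterior concentrations are ``alpha + counts``."""
    return DirichletSpec(
        alpha_nd=spec.alpha_nd + spec.f_nd,
        alpha_d=spec.alpha_d + spec.f_d,
        f_nd=np.zeros(spec.m, dtype=int),
        f_d=np.zeros(spec.m, dtype=int),
    )


def auc_discrete(pair: ProbPair) -> float:
    """``AUC = sum_i (1 - F_D(c_i)) p_NDi`` — P(X_D > X_ND), ties count 0."""
    fd = np.cumsum(pair.p_d)
    return float(np.sum((1.0 - fd) * pair.p_nd))


def _auc_from_matrices(p_nd: np.ndarray, p_d: np.ndarray) -> np.ndarray:
    """Row-wise AUC for (N, m) matrices of probability vectors."""
    fd = np.cumsum(p_d, axis=1)
    return ((1.0 - fd) * p_nd).sum(axis=1)


@dataclass
class RatesTable:
    """Per-cutoff conditional rates and the Error-minimizing cutoff."""

    scale: CategoryScale
    fnr: np.ndarray
    fpr: np.ndarray
    error: np.ndarray
    profiles: list[ErrorProfile]
    copt: float
    copt_index: int

    @property
    def profile_at_copt(self) -> ErrorProfile:
        return self.profiles[self.copt_index]


def rates_and_copt(
    pair: ProbPair, w: float, scale: CategoryScale | None = None
) -> RatesTable:
    """FNR/FPR at each cutpoint, full error profiles, and the cutoff
    minimizing ``Error = w FNR + (1-w) FPR`` (ties to the smallest)."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    if scale is None:
        scale = CategoryScale.integer(pair.m)
    if scale.m != pair.m:
        raise ValueError("scale length must match probability vectors")
    fnr = np.cumsum(pair.p_d)
    fpr = 1.0 - np.cumsum(pair.p_nd)
    err = w * fnr + (1.0 - w) * fpr
    idx = int(np.argmin(err))  # argmin returns the first (smallest cutoff)
    profiles = [error_profile(fn, fp, w) for fn, fp in zip(fnr, fpr)]
    return RatesTable(
        scale=scale, fnr=fnr, fpr=fpr, error=err, profiles=profiles,
        copt=float(scale.cutpoints[idx]), copt_index=idx,
    )


def monotone_matrix(k: int, direction: str = "nonincreasing") -> np.ndarray:
    """Linear map sending the simplex onto the monotone probability vectors.

    For the nonincreasing case row ``i`` is ``(0,...,0, 1/i, 1/(i+1), ...,
    1/k)`` so ``p_i = sum_{j>=i} omega_j / j``; the nondecreasing map is the
    row reversal (cross-diagonal permutation) of the same matrix.
    """
    A = np.zeros((k, k))
    for i in range(k):
        A[i, i:] = 1.0 / np.arange(i + 1, k + 1)
    if direction == "nonincreasing":
        return A
    if direction == "nondecreasing":
        return A[::-1]
    raise ValueError("direction must be 'nonincreasing' or 'nondecreasing'")


def monotone_from_simplex(omega, direction: str = "nonincreasing") -> np.ndarray:
    """Map a simplex point to a monotone probability vector.

    A uniform ``omega`` induces the uniform distribution on the set of
    monotone probability vectors, which is the natural prior when the
    category probabilities are believed ordered.
    """
    om = np.asarray(omega, dtype=float)
    if om.ndim != 1 or np.any(om < 0) or not math.isclose(om.sum(), 1.0,
                                                          abs_tol=1e-9):
        raise ValueError("omega must be a probability vector")
    return monotone_matrix(om.size, direction) @ om


def sample_monotone_probabilities(
    k: int, n: int, rng: np.random.Generator, direction: str = "nonincreasing"
) -> np.ndarray:
    """Draw ``n`` vectors uniformly from the monotone probability vectors."""
    omega = rng.dirichlet(np.ones(k), n)
    return omega @ monotone_matrix(k, direction).T


@dataclass
class RateInference:
    """Second-stage RB inference for one error characteristic at the fixed
    estimated cutoff."""

    summary: RelativeBeliefSummary
    estimate: float
    plausible_interval: tuple[float, float]
    plausible_content: float
    undefined_prior_frac: float
    undefined_posterior_frac: float


@dataclass
class DiscreteReport:
    """Full inferential sequence for the ordered-discrete model."""

    h0: EvidenceAssessment
    conditioned: bool
    acceptance_prior: float
    acceptance_posterior: float
    auc: RelativeBeliefSummary
    copt: FiniteSupportRB
    error_characteristics: dict[str, RateInference]
    prevalence: rb_core.BetaPrevalenceInference | None
    prevalence_mode: str  # "known" | "prior-only" | "posterior"
    settings: dict


def _rate_rb(prior_vals, post_vals, L) -> RateInference:
    """Discretize one rate on (0, 1] under prior and posterior and form RB,
    dropping undefined (nan) draws."""
    pv = np.asarray(prior_vals, dtype=float)
    qv = np.asarray(post_vals, dtype=float)
    p_ok, q_ok = ~np.isnan(pv), ~np.isnan(qv)
    summ = relative_belief(
        discretize(np.clip(pv[p_ok], 0.0, 1.0), L=L),
        discretize(np.clip(qv[q_ok], 0.0, 1.0), L=L),
    )
    return RateInference(
        summary=summ,
        estimate=summ.estimate,
        plausible_interval=summ.plausible_region,
        plausible_content=summ.plausible_content,
        undefined_prior_frac=float(1.0 - p_ok.mean()),
        undefined_posterior_frac=float(1.0 - q_ok.mean()),
    )


def _copt_indices(p_nd: np.ndarray, p_d: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise Error-minimizing cutoff index for matrices of draws."""
    fnr = np.cumsum(p_d, axis=1)
    fpr = 1.0 - np.cumsum(p_nd, axis=1)
    err = w[:, None] * fnr + (1.0 - w[:, None]) * fpr
    return np.argmin(err, axis=1)


def run_discrete_inference(
    f_nd,
    f_d,
    alpha_nd=None,
    alpha_d=None,
    scale: CategoryScale | None = None,
    prevalence: float | PrevalencePrior = 0.5,
    scheme: str = "i",
    N: int = DEFAULT_N,
    L: int = DEFAULT_L,
    seed: int = 0,
    condition: bool = True,
    acceptance_floor: float = 1e-3,
) -> DiscreteReport:
    """Run the full relative-belief ROC analysis for ordered-discrete data.

    Parameters
    ----------
    f_nd, f_d
        Category counts for the nondiseased and diseased samples.
    alpha_nd, alpha_d
        Dirichlet prior concentrations (default uniform, all ones).
    prevalence
        Either a known prevalence value, or an elicited
        :class:`~rbroc.elicitation.PrevalencePrior`.  With a prior, sampling
        ``scheme`` "i" (separate group samples) uses the prior only, while
        scheme "ii" (full-population sample) also updates the prior with the
        group totals to a posterior.
    condition
        After evidence in favor of ``AUC > 1/2`` is found, condition both
        prior and posterior samples on that event by rejection before the
        remaining inferences.

    The report carries the evidence assessment for ``AUC > 1/2``, RB
    inference for the AUC on an ``L``-bin grid over (0, 1], RB inference for
    the optimal cutoff on the finite scale (no discretization needed), and
    second-stage RB inferences for the error characteristics at the fixed
    estimated cutoff.
    """
    f_nd = np.asarray(f_nd)
    f_d = np.asarray(f_d)
    m = f_nd.size
    if alpha_nd is None:
        alpha_nd = np.ones(m)
    if alpha_d is None:
        alpha_d = np.ones(m)
    spec = DirichletSpec(alpha_nd, alpha_d, f_nd, f_d)
    post = posterior_dirichlet(spec)
    if scale is None:
        scale = CategoryScale.integer(m)
    if scheme not in ("i", "ii"):
        raise ValueError("scheme must be 'i' or 'ii'")

    rng = np.random.default_rng(seed)
    p_nd_prior = rng.dirichlet(spec.alpha_nd, N)
    p_d_prior = rng.dirichlet(spec.alpha_d, N)
    p_nd_post = rng.dirichlet(post.alpha_nd, N)
    p_d_post = rng.dirichlet(post.alpha_d, N)

    # prevalence draws for prior- and posterior-side computations
    prev_inf = None
    if isinstance(prevalence, PrevalencePrior):
        w_prior = prevalence.sample(N, rng)
        if scheme == "ii" and not prevalence.degenerate:
            n_d_tot, n_nd_tot = int(f_d.sum()), int(f_nd.sum())
            b1, b2 = prevalence.updated(n_d_tot, n_nd_tot)
            w_post = rng.beta(b1, b2, N)
            prev_inf = beta_binomial_rb(prevalence.alpha1, prevalence.alpha2,
                                        n_d_tot, n_nd_tot)
            prev_mode = "posterior"
        else:
            w_post = prevalence.sample(N, rng)
            prev_mode = "prior-only"
    else:
        w = float(prevalence)
        if not 0.0 <= w <= 1.0:
            raise ValueError("known prevalence must be in [0, 1]")
        w_prior = np.full(N, w)
        w_post = np.full(N, w)
        prev_mode = "known"

    auc_prior = _auc_from_matrices(p_nd_prior, p_d_prior)
    auc_post = _auc_from_matrices(p_nd_post, p_d_post)
    h0 = assess_event(auc_prior > 0.5, auc_post > 0.5)

    do_condition = condition and h0.direction == "favor"
    if do_condition:
        keep_prior = auc_prior > 0.5
        keep_post = auc_post > 0.5
        acc_prior = float(keep_prior.mean())
        acc_post = float(keep_post.mean())
        if min(acc_prior, acc_post) < acceptance_floor:
            raise RuntimeError(
                "rejection acceptance rate below floor "
                f"({min(acc_prior, acc_post):.2e}); consider priors "
                "concentrated on monotone probability vectors, which place "
                "more mass on AUC > 1/2"
            )
    else:
        keep_prior = np.ones(N, dtype=bool)
        keep_post = np.ones(N, dtype=bool)
        acc_prior = acc_post = 1.0

    p_nd_pr, p_d_pr, w_pr = (p_nd_prior[keep_prior], p_d_prior[keep_prior],
                             w_prior[keep_prior])
    p_nd_po, p_d_po, w_po = (p_nd_post[keep_post], p_d_post[keep_post],
                             w_post[keep_post])

    auc_summary = relative_belief(
        discretize(auc_prior[keep_prior], L=L),
        discretize(auc_post[keep_post], L=L),
    )

    idx_prior = _copt_indices(p_nd_pr, p_d_pr, w_pr)
    idx_post = _copt_indices(p_nd_po, p_d_po, w_po)
    copt_summary = finite_relative_belief(
        np.asarray(scale.cutpoints),
        np.bincount(idx_prior, minlength=m) / idx_prior.size,
        np.bincount(idx_post, minlength=m) / idx_post.size,
    )

    # second stage: error characteristics at the fixed estimated cutoff,
    # reusing the conditioned draws
    j = copt_summary.estimate_index
    rates: dict[str, RateInference] = {}
    for name, vals in _rate_draws(p_nd_pr, p_d_pr, w_pr, j).items():
        rates[name] = [vals]
    for name, vals in _rate_draws(p_nd_po, p_d_po, w_po, j).items():
        rates[name].append(vals)
    characteristics = {
        name: _rate_rb(prior_vals, post_vals, L)
        for name, (prior_vals, post_vals) in rates.items()
    }

    return DiscreteReport(
        h0=h0,
        conditioned=do_condition,
        acceptance_prior=acc_prior,
        acceptance_posterior=acc_post,
        auc=auc_summary,
        copt=copt_summary,
        error_characteristics=characteristics,
        prevalence=prev_inf,
        prevalence_mode=prev_mode,
        settings={"N": N, "L": L, "seed": seed, "scheme": scheme,
                  "m": m, "condition": condition},
    )


def _rate_draws(p_nd, p_d, w, j) -> dict[str, np.ndarray]:
    """Per-draw error characteristics at cutoff index ``j``."""
    fnr = np.cumsum(p_d, axis=1)[:, j]
    fpr = 1.0 - np.cumsum(p_nd, axis=1)[:, j]
    err = w * fnr + (1.0 - w) * fpr
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(
            (den_pos := w * (1 - fnr) + (1 - w) * fpr) > 0,
            (1 - w) * fpr / den_pos, np.nan,
        )
        fndr = np.where(
            (den_neg := w * fnr + (1 - w) * (1 - fpr)) > 0,
            w * fnr / den_neg, np.nan,
        )
    return {"fnr": fnr, "fpr": fpr, "error": err, "fdr": fdr, "fndr": fndr}
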