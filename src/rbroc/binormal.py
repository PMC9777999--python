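"""Binormal diagnostic model with conjugate normal-gamma priors.

Both group distributions are normal, ``F_ND = N(mu_ND, sigma2_ND)`` and
``F_D = N(mu_D, sigma2_D)``, either with a common variance (equal-variance
variant, one pooled precision) or with separate variances.  The conjugate
prior is normal-gamma: ``mu | sigma^2 ~ N(mu0, tau0^2 sigma^2)`` and
``1/sigma^2 ~ gamma(lambda1, lambda2)``.

Closed forms drive much of the analysis:

* ``AUC = int Phi((mu_D - mu_ND)/sigma_D + (sigma_ND/sigma_D) z) phi(z) dz``
  (evaluated by Gauss-Hermite quadrature; it equals
  ``Phi((mu_D-mu_ND)/sqrt(sigma2_D+sigma2_ND))``, used as a cross-check);
* the Error-minimizing cutoff: with equal variances a finite cutoff exists
  iff ``mu_D > mu_ND`` and equals
  ``(mu_D+mu_ND)/2 + sigma^2/(mu_D-mu_ND) * log((1-w)/w)``;
  with unequal variances it exists iff the discriminant
  ``(mu_D-mu_ND)^2 + 2(sigma2_D-sigma2_ND) log(((1-w)/w) sigma_D/sigma_ND)``
  is nonnegative, and the closed form picks the stationary local minimum of
  Error(c).  The two requirements (mean ordering and discriminant) combine
  into a single positivity condition assessed as the first hypothesis in
  the unequal-variance analysis.

Because the cutoff distributions are extremely long-tailed, cutoff
inference is carried out on the bounded ``cmod = 1/2 + arctan(c)/pi``
scale (the Cauchy cdf, mapping +inf to 1) and back-transformed; relative
belief inferences are invariant to this reparameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .elicitation import NormalGammaParams, PrevalencePrior
from . import rb_core
from .rb_core import (
    DEFAULT_L,
    DEFAULT_N,
    EvidenceAssessment,
    RelativeBeliefSummary,
    assess_event,
    beta_binomial_rb,
    discretize,
    relative_belief,
)

__all__ = [
    "BinormalParams",
    "SummaryStats",
    "CutoffResult",
    "NormalGammaState",
    "EqualVarState",
    "UnequalVarState",
    "ConditionalDraws",
    "CutoffInference",
    "BinormalReport",
    "update_conjugate",
    "auc_binormal",
    "auc_binormal_closed_form",
    "copt_closed_form",
    "positivity_condition",
    "nonexistence_threshold",
    "conditional_samples",
    "run_binormal_inference",
    "cmod_transform",
    "cmod_inverse",
]

_GH_NODES = 64
_gh_x, _gh_w = np.polynomial.hermite.hermgauss(_GH_NODES)


@dataclass(frozen=True)
class BinormalParams:
    """Group means and variances of the binormal model."""

    mu_nd: float
    mu_d: float
    sigma2_nd: float
    sigma2_d: float

    def __post_init__(self) -> None:
        if self.sigma2_nd <= 0 or self.sigma2_d <= 0:
            raise ValueError("variances must be positive")

    @classmethod
    def equal_variance(cls, mu_nd, mu_d, sigma2) -> "BinormalParams":
        return cls(mu_nd, mu_d, sigma2, sigma2)


@dataclass(frozen=True)
class SummaryStats:
    """Sufficient statistics of one group: size, mean and the sum of
    squared deviations ``ss = ||x - xbar 1||^2``."""

    n: int
    mean: float
    ss: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if self.ss < 0:
            raise ValueError("sum of squared deviations must be nonnegative")

    @classmethod
    def from_data(cls, x) -> "SummaryStats":
        x = np.asarray(x, dtype=float)
        if x.size == 0:
            return cls(0, 0.0, 0.0)
        return cls(int(x.size), float(x.mean()),
                   float(np.sum((x - x.mean()) ** 2)))


@dataclass(frozen=True)
class CutoffResult:
    """Optimal cutoff with its bounded reparameterization and existence."""

    copt: float  # +inf when no finite cutoff exists
    cmod: float
    exists: bool


def cmod_transform(c) -> np.ndarray | float:
    """Cauchy-cdf compression ``cmod = 1/2 + arctan(c)/pi``; ``+inf -> 1``."""
    c = np.asarray(c, dtype=float)
    out = 0.5 + np.arctan(c) / np.pi
    out = np.where(np.isposinf(c), 1.0, out)
    out = np.where(np.isneginf(c), 0.0, out)
    return float(out) if out.ndim == 0 else out


def cmod_inverse(v) -> np.ndarray | float:
    v = np.asarray(v, dtype=float)
    out = np.where(v >= 1.0, np.inf,
                   np.where(v <= 0.0, -np.inf, np.tan(np.pi * (v - 0.5))))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# conjugate updates

@dataclass(frozen=True)
class NormalGammaState:
    """One normal-gamma block: ``mu | sigma^2 ~ N(mean, kappa sigma^2)``,
    ``1/sigma^2 ~ gamma(shape, rate)``.  Serves as both prior and
    posterior."""

    mean: float
    kappa: float
    shape: float
    rate: float


@dataclass(frozen=True)
class EqualVarState:
    """Joint state of the equal-variance model (one pooled precision)."""

    nd: NormalGammaState
    d: NormalGammaState
    shape: float
    rate: float


@dataclass(frozen=True)
class UnequalVarState:
    nd: NormalGammaState
    d: NormalGammaState


def _prior_block(prior: NormalGammaParams) -> NormalGammaState:
    return NormalGammaState(prior.mu0, prior.tau0**2, prior.lambda1,
                            prior.lambda2)


def prior_state(prior: NormalGammaParams, variant: str):
    """Express the normal-gamma prior in the same state form as posteriors."""
    blk = _prior_block(prior)
    if variant == "equal":
        return EqualVarState(nd=blk, d=blk, shape=prior.lambda1,
                             rate=prior.lambda2)
    if variant == "unequal":
        return UnequalVarState(nd=blk, d=blk)
    raise ValueError("variant must be 'equal' or 'unequal'")


def _mean_update(prior: NormalGammaParams, s: SummaryStats):
    inv_t2 = 1.0 / prior.tau0**2
    kappa = 1.0 / (s.n + inv_t2)
    mean = kappa * (s.n * s.mean + prior.mu0 * inv_t2)
    shift = kappa * (s.n * inv_t2) * (s.mean - prior.mu0) ** 2 / 2.0
    return mean, kappa, shift


def update_conjugate(
    prior: NormalGammaParams,
    stats_nd: SummaryStats,
    stats_d: SummaryStats,
    variant: str = "equal",
):
    """Exact conjugate posterior update from group summary statistics.

    The equal-variance variant pools both groups for the precision:
    ``1/sigma^2 | data ~ gamma(lambda1 + (n_D + n_ND)/2, lambda_x)`` where
    ``lambda_x`` adds half the within-group sums of squares and the two
    shrinkage terms.  The unequal variant updates each group's normal-gamma
    block separately.  Empty data returns the prior state.
    """
    if variant == "equal":
        m_nd, k_nd, shift_nd = _mean_update(prior, stats_nd)
        m_d, k_d, shift_d = _mean_update(prior, stats_d)
        shape = prior.lambda1 + (stats_nd.n + stats_d.n) / 2.0
        rate = (prior.lambda2 + (stats_nd.ss + stats_d.ss) / 2.0
                + shift_d + shift_nd)
        return EqualVarState(
            nd=NormalGammaState(m_nd, k_nd, shape, rate),
            d=NormalGammaState(m_d, k_d, shape, rate),
            shape=shape, rate=rate,
        )
    if variant == "unequal":
        blocks = {}
        for key, s in (("nd", stats_nd), ("d", stats_d)):
            m, k, shift = _mean_update(prior, s)
            blocks[key] = NormalGammaState(
                mean=m, kappa=k,
                shape=prior.lambda1 + s.n / 2.0,
                rate=prior.lambda2 + s.ss / 2.0 + shift,
            )
        return UnequalVarState(nd=blocks["nd"], d=blocks["d"])
    raise ValueError("variant must be 'equal' or 'unequal'")


# ---------------------------------------------------------------------------
# AUC and optimal cutoff

def _auc_gh(mu_nd, mu_d, s2_nd, s2_d):
    """Gauss-Hermite quadrature of the AUC integral, vectorized over draws."""
    mu_nd, mu_d = np.asarray(mu_nd, float), np.asarray(mu_d, float)
    s_nd = np.sqrt(np.asarray(s2_nd, float))
    s_d = np.sqrt(np.asarray(s2_d, float))
    b = (mu_d - mu_nd) / s_d
    s = s_nd / s_d
    z = math.sqrt(2.0) * _gh_x  # substitution for the N(0,1) weight
    arg = b[..., None] + s[..., None] * z
    return (stats.norm.cdf(arg) @ _gh_w) / math.sqrt(math.pi)


def auc_binormal(params: BinormalParams) -> float:
    """AUC of the binormal model by quadrature of the defining integral."""
    return float(_auc_gh(params.mu_nd, params.mu_d,
                         params.sigma2_nd, params.sigma2_d))


def auc_binormal_closed_form(params: BinormalParams) -> float:
    """``Phi((mu_D - mu_ND)/sqrt(sigma2_D + sigma2_ND))`` (cross-check)."""
    return float(stats.norm.cdf(
        (params.mu_d - params.mu_nd)
        / math.sqrt(params.sigma2_d + params.sigma2_nd)
    ))


def _discriminant(mu_nd, mu_d, s2_nd, s2_d, w):
    return (mu_d - mu_nd) ** 2 + 2.0 * (s2_d - s2_nd) * np.log(
        ((1.0 - w) / w) * np.sqrt(s2_d / s2_nd)
    )


def copt_closed_form(
    params: BinormalParams, w: float, variant: str = "equal"
) -> CutoffResult:
    """Closed-form Error-minimizing cutoff.

    Equal variances: finite iff ``mu_D > mu_ND``.  Unequal variances:
    finite iff the discriminant is nonnegative; the returned root is the
    stationary local minimum of Error(c) for either variance ordering.
    """
    if not 0.0 < w < 1.0:
        raise ValueError("prevalence must be strictly inside (0, 1)")
    if variant == "equal":
        s2 = params.sigma2_d
        if params.mu_d <= params.mu_nd:
            return CutoffResult(math.inf, 1.0, False)
        c = ((params.mu_d + params.mu_nd) / 2.0
             + s2 / (params.mu_d - params.mu_nd) * math.log((1.0 - w) / w))
        return CutoffResult(float(c), cmod_transform(c), True)
    if variant == "unequal":
        s2_nd, s2_d = params.sigma2_nd, params.sigma2_d
        if math.isclose(s2_nd, s2_d, rel_tol=1e-12):
            return copt_closed_form(params, w, "equal")
        disc = _discriminant(params.mu_nd, params.mu_d, s2_nd, s2_d, w)
        if disc < 0:
            return CutoffResult(math.inf, 1.0, False)
        c = ((s2_nd * params.mu_d - s2_d * params.mu_nd) / (s2_nd - s2_d)
             - math.sqrt(s2_nd * s2_d) / (s2_nd - s2_d) * math.sqrt(disc))
        return CutoffResult(float(c), cmod_transform(c), True)
    raise ValueError("variant must be 'equal' or 'unequal'")


def _copt_equal_draws(mu_nd, mu_d, s2, w):
    """Vectorized equal-variance cutoff; requires mu_d > mu_nd elementwise."""
    return (mu_d + mu_nd) / 2.0 + s2 / (mu_d - mu_nd) * np.log((1.0 - w) / w)


def _copt_unequal_draws(mu_nd, mu_d, s2_nd, s2_d, w):
    disc = _discriminant(mu_nd, mu_d, s2_nd, s2_d, w)
    with np.errstate(invalid="ignore"):
        c = ((s2_nd * mu_d - s2_d * mu_nd) / (s2_nd - s2_d)
             - np.sqrt(s2_nd * s2_d) / (s2_nd - s2_d) * np.sqrt(disc))
    return np.where(disc >= 0, c, np.inf)


def positivity_condition(params: BinormalParams, w: float) -> tuple[float, bool]:
    """Combined condition for a usable classifier: mean ordering together
    with cutoff existence, expressed as a single quantity that must be
    nonnegative:

        mu_D - mu_ND - sqrt(max(0, -2(sigma2_D - sigma2_ND)
                                   log(((1-w)/w) sigma_D/sigma_ND)))
    """
    if not 0.0 < w < 1.0:
        raise ValueError("prevalence must be strictly inside (0, 1)")
    inner = -2.0 * (params.sigma2_d - params.sigma2_nd) * math.log(
        ((1.0 - w) / w) * math.sqrt(params.sigma2_d / params.sigma2_nd)
    )
    val = params.mu_d - params.mu_nd - math.sqrt(max(0.0, inner))
    return float(val), val >= 0.0


def _positivity_draws(mu_nd, mu_d, s2_nd, s2_d, w):
    inner = -2.0 * (s2_d - s2_nd) * np.log(
        ((1.0 - w) / w) * np.sqrt(s2_d / s2_nd)
    )
    return (mu_d - mu_nd - np.sqrt(np.maximum(0.0, inner))) >= 0.0


def nonexistence_threshold(params: BinormalParams) -> float | None:
    """Boundary prevalence at which the unequal-variance existence
    condition flips, found by root finding on the discriminant; ``None``
    when the discriminant never changes sign (including equal variances,
    where existence does not depend on ``w``)."""
    if math.isclose(params.sigma2_nd, params.sigma2_d, rel_tol=1e-12):
        return None
    f = lambda w: _discriminant(params.mu_nd, params.mu_d,
                                params.sigma2_nd, params.sigma2_d, w)
    eps = 1e-12
    if f(eps) * f(1 - eps) > 0:
        return None
    return float(optimize.brentq(f, eps, 1 - eps, xtol=1e-12))


# ---------------------------------------------------------------------------
# conditional sampling

@dataclass
class ConditionalDraws:
    """Monte Carlo draws from a prior/posterior conditioned on an event.

    Equal-variance mean-ordering conditioning is done by importance
    sampling (truncated-normal inversion for ``mu_ND`` with weight
    ``Phi((mu_D - mean_ND)/(tau sigma))``); the unequal-variance positivity
    event, which involves the prevalence, is done by rejection, giving
    uniform weights over the accepted draws.
    """

    mu_nd: np.ndarray
    mu_d: np.ndarray
    sigma2_nd: np.ndarray
    sigma2_d: np.ndarray
    weights: np.ndarray  # self-normalized
    w: np.ndarray | None  # prevalence draws aligned with the parameters
    ess: float
    acceptance: float | None
    event: str


def conditional_samples(
    state,
    event: str,
    N: int,
    rng: np.random.Generator,
    w_draws: np.ndarray | None = None,
    ess_floor: float = 0.01,
) -> ConditionalDraws:
    """Sample a normal-gamma state conditioned on an event.

    ``event = "muD_gt_muND"`` (equal-variance state): draw the pooled
    variance, then ``mu_D``, then ``mu_ND`` from its normal truncated to
    ``(-inf, mu_D]`` by inverse-cdf, attaching the self-normalized weight
    ``Phi((mu_D - mean_ND) / (sqrt(kappa_ND) sigma))``.

    ``event = "eq8"`` (unequal-variance state): joint rejection of the
    parameter draws and the prevalence draws ``w_draws`` on the positivity
    event.
    """
    if event == "muD_gt_muND":
        if not isinstance(state, EqualVarState):
            raise ValueError("mean-ordering conditioning needs the "
                             "equal-variance state")
        s2 = 1.0 / rng.gamma(state.shape, 1.0 / state.rate, N)
        s = np.sqrt(s2)
        mu_d = rng.normal(state.d.mean, np.sqrt(state.d.kappa) * s)
        z = (mu_d - state.nd.mean) / (np.sqrt(state.nd.kappa) * s)
        raw_w = stats.norm.cdf(z)
        u = rng.uniform(0.0, 1.0, N)
        mu_nd = state.nd.mean + np.sqrt(state.nd.kappa) * s * stats.norm.ppf(
            u * raw_w
        )
        weights = raw_w / raw_w.sum()
        ess = 1.0 / float((weights**2).sum())
        if ess < ess_floor * N:
            raise RuntimeError(
                f"effective sample size {ess:.0f} below {ess_floor:.0%} of N"
            )
        wv = None if w_draws is None else np.asarray(w_draws, float)[:N]
        return ConditionalDraws(mu_nd, mu_d, s2, s2, weights, wv, ess, None,
                                event)
    if event == "eq8":
        if not isinstance(state, UnequalVarState):
            raise ValueError("positivity conditioning needs the "
                             "unequal-variance state")
        if w_draws is None:
            raise ValueError("the positivity event involves the prevalence; "
                             "w_draws is required")
        s2_nd = 1.0 / rng.gamma(state.nd.shape, 1.0 / state.nd.rate, N)
        s2_d = 1.0 / rng.gamma(state.d.shape, 1.0 / state.d.rate, N)
        mu_nd = rng.normal(state.nd.mean,
                           np.sqrt(state.nd.kappa * s2_nd))
        mu_d = rng.normal(state.d.mean, np.sqrt(state.d.kappa * s2_d))
        wv = np.asarray(w_draws, dtype=float)[:N]
        keep = _positivity_draws(mu_nd, mu_d, s2_nd, s2_d, wv)
        acc = float(keep.mean())
        if acc < ess_floor:
            raise RuntimeError(
                f"rejection acceptance rate {acc:.2%} below {ess_floor:.0%}"
            )
        n_keep = int(keep.sum())
        weights = np.full(n_keep, 1.0 / n_keep)
        return ConditionalDraws(
            mu_nd[keep], mu_d[keep], s2_nd[keep], s2_d[keep], weights,
            wv[keep], float(n_keep), acc, event,
        )
    raise ValueError("event must be 'muD_gt_muND' or 'eq8'")


def _unconditional_draws(state, N, rng):
    if isinstance(state, EqualVarState):
        s2 = 1.0 / rng.gamma(state.shape, 1.0 / state.rate, N)
        s = np.sqrt(s2)
        mu_nd = rng.normal(state.nd.mean, np.sqrt(state.nd.kappa) * s)
        mu_d = rng.normal(state.d.mean, np.sqrt(state.d.kappa) * s)
        return mu_nd, mu_d, s2, s2
    s2_nd = 1.0 / rng.gamma(state.nd.shape, 1.0 / state.nd.rate, N)
    s2_d = 1.0 / rng.gamma(state.d.shape, 1.0 / state.d.rate, N)
    mu_nd = rng.normal(state.nd.mean, np.sqrt(state.nd.kappa * s2_nd))
    mu_d = rng.normal(state.d.mean, np.sqrt(state.d.kappa * s2_d))
    return mu_nd, mu_d, s2_nd, s2_d


# ---------------------------------------------------------------------------
# cutoff inference on the cmod scale

@dataclass
class CutoffInference:
    """RB inference for the optimal cutoff carried out on the cmod scale.

    The grid has ``L`` equal-width bins on (0, 1) plus an explicit atom at
    1 collecting draws with no finite cutoff; estimates and plausible
    ranges are back-transformed to the cutoff scale.
    """

    L: int
    support_cmod: np.ndarray  # L midpoints then the atom at 1.0
    prior_mass: np.ndarray
    posterior_mass: np.ndarray
    rb: np.ndarray
    estimate_cmod: float
    estimate: float  # cutoff scale; +inf when the atom maximizes RB
    plausible_cmod: tuple[float, float]
    plausible_interval: tuple[float, float]  # cutoff scale hull
    plausible_content: float
    atom_prior: float
    atom_posterior: float


def _cmod_histogram(values, weights, L):
    v = np.asarray(values, dtype=float)
    atom = v >= 1.0 - 1e-12
    idx = np.clip(np.ceil(v * L).astype(int) - 1, 0, L - 1)
    idx = np.where(atom, L, idx)
    if weights is None:
        weights = np.full(v.size, 1.0 / v.size)
    mass = np.bincount(idx, weights=weights, minlength=L + 1)
    return mass / mass.sum()


def _smooth_regular_bins(mass: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over the L regular bins (atom untouched),
    preserving their total mass."""
    if window <= 1:
        return mass
    body, atom = mass[:-1], mass[-1]
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(body, pad, mode="edge")
    sm = np.convolve(padded, kernel, mode="valid")
    if body.sum() > 0:
        sm = sm * (body.sum() / sm.sum())
    return np.concatenate([sm, [atom]])


def cutoff_rb_inference(
    prior_cmod,
    posterior_cmod,
    L: int = DEFAULT_L,
    prior_weights=None,
    posterior_weights=None,
    smooth_window: int | None = None,
) -> CutoffInference:
    """RB inference for the cutoff from cmod-scale draws of both samples.

    ``smooth_window`` applies a centered moving average to the *posterior*
    histogram (the remedy for the irregular multimodal posterior arising
    with discrete data atoms); the prior is left unsmoothed.
    """
    p = _cmod_histogram(prior_cmod, prior_weights, L)
    q = _cmod_histogram(posterior_cmod, posterior_weights, L)
    if smooth_window:
        q = _smooth_regular_bins(q, smooth_window)
    mids = (np.arange(1, L + 1) - 0.5) / L
    support = np.concatenate([mids, [1.0]])
    rb = np.full(L + 1, np.nan)
    pos = p > 0
    rb[pos] = q[pos] / p[pos]
    rb[(~pos) & (q > 0)] = np.inf
    cand = np.where(np.isfinite(rb), rb, -np.inf)
    est_idx = int(np.argmax(cand))
    plaus = np.nan_to_num(rb, nan=0.0) > 1.0
    cm_lo = float(support[plaus].min()) if plaus.any() else math.nan
    cm_hi = float(support[plaus].max()) if plaus.any() else math.nan
    return CutoffInference(
        L=L,
        support_cmod=support,
        prior_mass=p,
        posterior_mass=q,
        rb=rb,
        estimate_cmod=float(support[est_idx]),
        estimate=float(cmod_inverse(support[est_idx])),
        plausible_cmod=(cm_lo, cm_hi),
        plausible_interval=(float(cmod_inverse(cm_lo)),
                            float(cmod_inverse(cm_hi))),
        plausible_content=float(q[plaus].sum()),
        atom_prior=float(p[-1]),
        atom_posterior=float(q[-1]),
    )


# ---------------------------------------------------------------------------
# full analysis

@dataclass
class RateInference:
    summary: RelativeBeliefSummary
    estimate: float
    plausible_interval: tuple[float, float]
    plausible_content: float
    undefined_prior_frac: float
    undefined_posterior_frac: float


def rate_rb(prior_vals, post_vals, L, prior_weights=None,
            post_weights=None) -> RateInference:
    """RB inference for one rate on (0, 1], dropping undefined draws."""
    pv = np.asarray(prior_vals, dtype=float)
    qv = np.asarray(post_vals, dtype=float)
    p_ok, q_ok = ~np.isnan(pv), ~np.isnan(qv)
    pw = None if prior_weights is None else np.asarray(prior_weights)[p_ok]
    qw = None if post_weights is None else np.asarray(post_weights)[q_ok]
    summ = relative_belief(
        discretize(np.clip(pv[p_ok], 0.0, 1.0), L=L, weights=pw),
        discretize(np.clip(qv[q_ok], 0.0, 1.0), L=L, weights=qw),
    )
    return RateInference(
        summary=summ,
        estimate=summ.estimate,
        plausible_interval=summ.plausible_region,
        plausible_content=summ.plausible_content,
        undefined_prior_frac=float(1.0 - p_ok.mean()),
        undefined_posterior_frac=float(1.0 - q_ok.mean()),
    )


@dataclass
class BinormalReport:
    h0: EvidenceAssessment
    conditioned: bool
    auc: RelativeBeliefSummary
    cutoff: CutoffInference
    error_characteristics: dict[str, RateInference]
    prevalence: rb_core.BetaPrevalenceInference | None
    prevalence_mode: str
    prior_ess: float
    posterior_ess: float
    settings: dict


def _prevalence_draws(prevalence, scheme, n_d, n_nd, N, rng):
    if isinstance(prevalence, PrevalencePrior):
        w_prior = prevalence.sample(N, rng)
        if scheme == "ii" and not prevalence.degenerate:
            b1, b2 = prevalence.updated(n_d, n_nd)
            w_post = rng.beta(b1, b2, N)
            inf = beta_binomial_rb(prevalence.alpha1, prevalence.alpha2,
                                   n_d, n_nd)
            return w_prior, w_post, inf, "posterior"
        return w_prior, prevalence.sample(N, rng), None, "prior-only"
    w = float(prevalence)
    if not 0.0 < w < 1.0:
        raise ValueError("known prevalence must be strictly inside (0, 1)")
    return np.full(N, w), np.full(N, w), None, "known"


def _rates_at_cutoff(c, mu_nd, mu_d, s2_nd, s2_d, w):
    fnr = stats.norm.cdf((c - mu_d) / np.sqrt(s2_d))
    fpr = 1.0 - stats.norm.cdf((c - mu_nd) / np.sqrt(s2_nd))
    err = w * fnr + (1.0 - w) * fpr
    with np.errstate(divide="ignore", invalid="ignore"):
        den_pos = w * (1 - fnr) + (1 - w) * fpr
        den_neg = w * fnr + (1 - w) * (1 - fpr)
        fdr = np.where(den_pos > 0, (1 - w) * fpr / den_pos, np.nan)
        fndr = np.where(den_neg > 0, w * fnr / den_neg, np.nan)
    return {"fnr": fnr, "fpr": fpr, "error": err, "fdr": fdr, "fndr": fndr}


def run_binormal_inference(
    stats_nd: SummaryStats,
    stats_d: SummaryStats,
    prior: NormalGammaParams,
    prevalence: float | PrevalencePrior,
    variant: str = "equal",
    scheme: str = "ii",
    N: int = DEFAULT_N,
    L: int = DEFAULT_L,
    cmod_L: int | None = None,
    seed: int = 0,
    condition: bool = True,
) -> BinormalReport:
    """Full relative-belief ROC analysis under the binormal model.

    The inferential sequence: (1) assess the first hypothesis — the mean
    ordering ``mu_D > mu_ND`` for equal variances (prior probability
    exactly 1/2 under the exchangeable prior), or the positivity condition
    for unequal variances (integrating the prevalence prior/posterior);
    (2) if favored, condition prior and posterior on the event and infer
    the AUC on an ``L``-bin grid; (3) infer the optimal cutoff on the cmod
    scale and back-transform; (4) exact RB inference for the prevalence
    under sampling scheme "ii"; (5) second-stage RB inference for the
    error characteristics at the fixed estimated cutoff.
    """
    if variant not in ("equal", "unequal"):
        raise ValueError("variant must be 'equal' or 'unequal'")
    if scheme not in ("i", "ii"):
        raise ValueError("scheme must be 'i' or 'ii'")
    cmod_L = L if cmod_L is None else cmod_L
    rng = np.random.default_rng(seed)
    st_prior = prior_state(prior, variant)
    st_post = update_conjugate(prior, stats_nd, stats_d, variant)
    w_prior, w_post, prev_inf, prev_mode = _prevalence_draws(
        prevalence, scheme, stats_d.n, stats_nd.n, N, rng
    )

    # --- stage 1: hypothesis assessment on unconditioned draws
    pr_draws = _unconditional_draws(st_prior, N, rng)
    po_draws = _unconditional_draws(st_post, N, rng)
    if variant == "equal":
        ind_prior = pr_draws[1] > pr_draws[0]
        ind_post = po_draws[1] > po_draws[0]
        h0 = assess_event(ind_prior, ind_post, prior_prob=0.5)
        event = "muD_gt_muND"
    else:
        ind_prior = _positivity_draws(*pr_draws, w_prior)
        ind_post = _positivity_draws(*po_draws, w_post)
        h0 = assess_event(ind_prior, ind_post)
        event = "eq8"

    do_condition = condition and h0.direction == "favor"
    if do_condition:
        cond_prior = conditional_samples(st_prior, event, N, rng,
                                         w_draws=w_prior)
        cond_post = conditional_samples(st_post, event, N, rng,
                                        w_draws=w_post)
        if variant == "equal":
            cond_prior.w = w_prior[:cond_prior.mu_nd.size]
            cond_post.w = w_post[:cond_post.mu_nd.size]
    else:
        def _as_cond(draws, wv):
            n = draws[0].size
            return ConditionalDraws(*draws, np.full(n, 1.0 / n), wv,
                                    float(n), 1.0, "none")
        cond_prior = _as_cond(pr_draws, w_prior)
        cond_post = _as_cond(po_draws, w_post)

    # --- stage 2: AUC inference (quadrature of the defining integral)
    auc_prior = _auc_gh(cond_prior.mu_nd, cond_prior.mu_d,
                        cond_prior.sigma2_nd, cond_prior.sigma2_d)
    auc_post = _auc_gh(cond_post.mu_nd, cond_post.mu_d,
                       cond_post.sigma2_nd, cond_post.sigma2_d)
    auc_summary = relative_belief(
        discretize(np.clip(auc_prior, 0, 1), L=L, weights=cond_prior.weights),
        discretize(np.clip(auc_post, 0, 1), L=L, weights=cond_post.weights),
    )

    # --- stage 3: cutoff inference on the cmod scale
    def _copt(c: ConditionalDraws):
        if variant == "equal":
            return _copt_equal_draws(c.mu_nd, c.mu_d, c.sigma2_d, c.w)
        return _copt_unequal_draws(c.mu_nd, c.mu_d, c.sigma2_nd,
                                   c.sigma2_d, c.w)

    cutoff = cutoff_rb_inference(
        cmod_transform(_copt(cond_prior)),
        cmod_transform(_copt(cond_post)),
        L=cmod_L,
        prior_weights=cond_prior.weights,
        posterior_weights=cond_post.weights,
    )

    # --- stage 5: error characteristics at the fixed estimated cutoff
    c_hat = cutoff.estimate
    characteristics: dict[str, RateInference] = {}
    if math.isfinite(c_hat):
        r_prior = _rates_at_cutoff(c_hat, cond_prior.mu_nd, cond_prior.mu_d,
                                   cond_prior.sigma2_nd, cond_prior.sigma2_d,
                                   cond_prior.w)
        r_post = _rates_at_cutoff(c_hat, cond_post.mu_nd, cond_post.mu_d,
                                  cond_post.sigma2_nd, cond_post.sigma2_d,
                                  cond_post.w)
        for name in r_prior:
            characteristics[name] = rate_rb(
                r_prior[name], r_post[name], L,
                prior_weights=cond_prior.weights,
                post_weights=cond_post.weights,
            )

    return BinormalReport(
        h0=h0,
        conditioned=do_condition,
        auc=auc_summary,
        cutoff=cutoff,
        error_characteristics=characteristics,
        prevalence=prev_inf if scheme == "ii" else None,
        prevalence_mode=prev_mode,
        prior_ess=cond_prior.ess,
        posterior_ess=cond_post.ess,
        settings={"N": N, "L": L, "cmod_L": cmod_L, "seed": seed,
                  "variant": variant, "scheme": scheme,
                  "condition": condition},
    )
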