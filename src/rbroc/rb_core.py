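"""Generic relative-belief inference engine.

The relative belief ratio of a value ``psi`` of a quantity of interest is the
ratio of its posterior to its prior density,

    RB(psi | x) = pi(psi | x) / pi(psi),

and the *principle of evidence* reads RB > 1 as evidence in favour of ``psi``
and RB < 1 as evidence against.  Everything in this module is built from
Monte Carlo samples of the quantity under its prior and posterior:
continuous quantities are discretized into equal-width histogram bins and
the RB ratio is formed bin by bin; finite discrete quantities use their
support directly.

The derived inferences are

* the *relative belief estimate*: the value maximizing RB;
* the *plausible region* ``{psi : RB(psi|x) > 1}`` and its posterior content,
  which quantifies the accuracy of the estimate;
* *credible regions* ``{psi : RB(psi|x) > c_gamma}`` nested inside the
  plausible region;
* hypothesis assessments for events, reporting RB together with the
  strength of the evidence.

All inferences are invariant under smooth increasing reparameterizations,
which the model modules exploit (e.g. cutoff inference on a bounded scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "GridDensity",
    "RelativeBeliefSummary",
    "FiniteSupportRB",
    "EvidenceAssessment",
    "BetaPrevalenceInference",
    "discretize",
    "relative_belief",
    "finite_relative_belief",
    "credible_region",
    "assess_event",
    "beta_binomial_rb",
]

#: default number of histogram bins for quantities on (0, 1]
DEFAULT_L = 25

#: default Monte Carlo sample size
DEFAULT_N = 100_000


@dataclass
class GridDensity:
    """Histogram estimate of a distribution on equal-width bins of a bounded
    interval.

    Bin ``i`` (1-based) is the half-open interval
    ``(lower + (i-1)h, lower + ih]`` with ``h = (upper-lower)/L``; all of its
    mass is assigned to the midpoint ``lower + (i - 1/2) h``.
    """

    lower: float
    upper: float
    L: int
    masses: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.L < 2:
            raise ValueError("at least 2 bins are required")
        if self.masses.shape != (self.L,):
            raise ValueError("masses must have length L")
        if np.any(self.masses < 0):
            raise ValueError("bin masses must be nonnegative")
        total = self.masses.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"bin masses must sum to 1 (got {total!r})")
        if not self.upper > self.lower:
            raise ValueError("upper must exceed lower")

    @property
    def width(self) -> float:
        return (self.upper - self.lower) / self.L

    @property
    def midpoints(self) -> np.ndarray:
        return self.lower + (np.arange(1, self.L + 1) - 0.5) * self.width

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.L + 1)

    def same_grid(self, other: "GridDensity") -> bool:
        return (
            self.L == other.L
            and math.isclose(self.lower, other.lower, abs_tol=1e-12)
            and math.isclose(self.upper, other.upper, abs_tol=1e-12)
        )


def discretize(
    samples,
    L: int = DEFAULT_L,
    lower: float = 0.0,
    upper: float = 1.0,
    weights=None,
) -> GridDensity:
    """Bin samples of a scalar quantity into a :class:`GridDensity`.

    Bins are lower-exclusive / upper-inclusive, matching the ``((i-1)/L, i/L]``
    discretization of (0, 1]; a sample exactly at ``lower`` is assigned to the
    first bin.  ``weights`` (e.g. self-normalized importance weights) default
    to uniform.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample list")
    if L < 2:
        raise ValueError("at least 2 bins are required")
    if np.any(x < lower) or np.any(x > upper):
        bad = x[(x < lower) | (x > upper)][0]
        raise ValueError(f"sample {bad!r} outside support [{lower}, {upper}]")
    h = (upper - lower) / L
    idx = np.ceil((x - lower) / h).astype(int) - 1
    idx = np.clip(idx, 0, L - 1)  # lower endpoint -> first bin
    if weights is None:
        masses = np.bincount(idx, minlength=L).astype(float) / x.size
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != x.shape:
            raise ValueError("weights must match samples")
        masses = np.bincount(idx, weights=w, minlength=L)
        masses = masses / masses.sum()
    return GridDensity(lower, upper, L, masses, x.size)


@dataclass
class RelativeBeliefSummary:
    """Relative belief ratios and derived inferences on a common grid.

    ``rb`` holds the bin-wise ratio of posterior to prior mass; bins with
    zero prior *and* zero posterior mass are marked ``nan`` and excluded from
    everything, while bins with zero prior but positive posterior mass are
    marked ``+inf`` and flagged in ``infinite_bins`` (a finite-Monte-Carlo
    artifact, excluded from the estimate unless requested).
    """

    prior: GridDensity
    posterior: GridDensity
    rb: np.ndarray
    estimate: float
    estimate_index: int
    tie_indices: np.ndarray
    plausible_bins: np.ndarray  # indices with RB > 1
    plausible_content: float
    infinite_bins: np.ndarray

    @property
    def plausible_region(self) -> tuple[float, float]:
        """Interval hull (lower edge, upper edge) of the plausible bins."""
        if self.plausible_bins.size == 0:
            return (math.nan, math.nan)
        edges = self.prior.edges
        return (
            float(edges[self.plausible_bins.min()]),
            float(edges[self.plausible_bins.max() + 1]),
        )

    @property
    def plausible_midpoint_span(self) -> tuple[float, float]:
        if self.plausible_bins.size == 0:
            return (math.nan, math.nan)
        mids = self.prior.midpoints[self.plausible_bins]
        return (float(mids.min()), float(mids.max()))


def relative_belief(
    prior: GridDensity,
    posterior: GridDensity,
    include_infinite: bool = False,
) -> RelativeBeliefSummary:
    """Form bin-wise RB ratios of two histograms on an identical grid.

    The estimate is the midpoint of the bin maximizing RB, ties broken to the
    smallest midpoint with all tied bins reported.  The plausible region
    consists of every bin with RB > 1 and its posterior content is the exact
    sum of posterior masses over those bins.
    """
    if not prior.same_grid(posterior):
        raise ValueError("prior and posterior must share the same grid")
    p, q = prior.masses, posterior.masses
    if np.all(p == 0):
        raise ValueError("all prior masses are zero")
    rb = np.full(prior.L, np.nan)
    pos = p > 0
    rb[pos] = q[pos] / p[pos]
    inf_bins = np.flatnonzero((~pos) & (q > 0))
    rb[inf_bins] = np.inf

    candidate = rb.copy()
    candidate[np.isnan(candidate)] = -np.inf
    if not include_infinite:
        candidate[inf_bins] = -np.inf
    best = candidate.max()
    ties = np.flatnonzero(candidate == best)
    est_idx = int(ties[0])

    plaus = np.flatnonzero(np.nan_to_num(rb, nan=0.0) > 1.0)
    content = float(q[plaus].sum())
    return RelativeBeliefSummary(
        prior=prior,
        posterior=posterior,
        rb=rb,
        estimate=float(prior.midpoints[est_idx]),
        estimate_index=est_idx,
        tie_indices=ties,
        plausible_bins=plaus,
        plausible_content=content,
        infinite_bins=inf_bins,
    )


@dataclass
class FiniteSupportRB:
    """Relative belief inference for a quantity on a finite support
    (e.g. the optimal cutoff over the ordered categories)."""

    support: np.ndarray
    prior_mass: np.ndarray
    posterior_mass: np.ndarray
    rb: np.ndarray
    estimate: float
    estimate_index: int
    plausible_set: np.ndarray  # support values with RB > 1
    plausible_content: float


def finite_relative_belief(
    support, prior_mass, posterior_mass
) -> FiniteSupportRB:
    """RB inference on a finite support; no discretization involved."""
    s = np.asarray(support, dtype=float)
    p = np.asarray(prior_mass, dtype=float)
    q = np.asarray(posterior_mass, dtype=float)
    if not (s.shape == p.shape == q.shape):
        raise ValueError("support and masses must have equal lengths")
    p = p / p.sum()
    q = q / q.sum()
    rb = np.full(s.size, np.nan)
    pos = p > 0
    rb[pos] = q[pos] / p[pos]
    rb[(~pos) & (q > 0)] = np.inf
    candidate = np.where(np.isfinite(rb), rb, -np.inf)
    est_idx = int(np.argmax(candidate))
    plaus_mask = np.nan_to_num(rb, nan=0.0) > 1.0
    return FiniteSupportRB(
        support=s,
        prior_mass=p,
        posterior_mass=q,
        rb=rb,
        estimate=float(s[est_idx]),
        estimate_index=est_idx,
        plausible_set=s[plaus_mask],
        plausible_content=float(q[plaus_mask].sum()),
    )


def credible_region(
    summary: RelativeBeliefSummary, gamma: float
) -> tuple[np.ndarray, float]:
    """gamma-relative-belief credible region ``{psi : RB(psi|x) > c_gamma}``.

    ``c_gamma`` is the largest threshold whose exceedance set has posterior
    content at least ``gamma``.  ``gamma`` may not exceed the posterior
    content of the plausible region, otherwise the region would contain
    values with evidence against them.  ``gamma = 0`` returns the empty
    region with ``c_gamma`` equal to the maximum RB, and
    ``gamma =`` plausible content returns the plausible region itself.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be a probability")
    if gamma > summary.plausible_content + 1e-12:
        raise ValueError(
            "gamma exceeds the posterior content of the plausible region; "
            "a credible region that large would include values with "
            "evidence against them"
        )
    rb = np.nan_to_num(summary.rb, nan=0.0, posinf=np.inf)
    q = summary.posterior.masses
    finite_vals = rb[np.isfinite(rb)]
    thresholds = np.concatenate([np.unique(finite_vals), [1.0]])
    thresholds = np.sort(thresholds)[::-1]
    for c in thresholds:
        region = np.flatnonzero(rb > c)
        if q[region].sum() >= gamma - 1e-12:
            return region, float(c)
    region = np.flatnonzero(rb > 1.0)  # pragma: no cover - gamma<=content
    return region, 1.0


@dataclass
class EvidenceAssessment:
    """Evidence about an event (hypothesis) from prior/posterior draws.

    ``rb`` is the ratio of posterior to prior probability of the event; its
    theoretical maximum is ``1 / prior_prob`` (``rb_max``).  For one-sided
    composite hypotheses the ``strength`` of the evidence is the posterior
    content of the event itself.
    """

    prior_prob: float
    posterior_prob: float
    rb: float
    strength: float
    direction: str  # "favor" | "against" | "neutral"
    rb_max: float
    prior_se: float
    posterior_se: float
    n_prior: int
    n_posterior: int
    prior_prob_analytic: bool = False


def _fraction(indicators, weights):
    ind = np.asarray(indicators, dtype=float).ravel()
    if ind.size == 0:
        raise ValueError("empty indicator list")
    if weights is None:
        p = ind.mean()
        n_eff = ind.size
    else:
        w = np.asarray(weights, dtype=float).ravel()
        w = w / w.sum()
        p = float(ind @ w)
        n_eff = 1.0 / float((w**2).sum())
    se = math.sqrt(max(p * (1 - p), 0.0) / n_eff)
    return float(p), se, ind.size


def assess_event(
    prior_draws,
    posterior_draws,
    prior_prob: float | None = None,
    prior_weights=None,
    posterior_weights=None,
) -> EvidenceAssessment:
    """Assess a hypothesis event from indicator draws.

    ``prior_draws`` / ``posterior_draws`` are boolean (0/1) indicators of the
    event under prior and posterior simulation.  When the prior probability
    of the event is known analytically (e.g. exactly 1/2 for mean ordering
    under an exchangeable prior) pass it as ``prior_prob``; Monte Carlo noise
    can otherwise push the reported RB above its theoretical maximum.
    """
    p_prior, se_prior, n_prior = _fraction(prior_draws, prior_weights)
    if prior_prob is not None:
        p_prior, se_prior, analytic = float(prior_prob), 0.0, True
    else:
        analytic = False
    p_post, se_post, n_post = _fraction(posterior_draws, posterior_weights)
    if p_prior <= 0:
        raise ValueError("hypothesis has no prior support (prior probability 0)")
    rb = p_post / p_prior
    if rb > 1:
        direction = "favor"
    elif rb < 1:
        direction = "against"
    else:
        direction = "neutral"
    return EvidenceAssessment(
        prior_prob=p_prior,
        posterior_prob=p_post,
        rb=rb,
        strength=p_post,
        direction=direction,
        rb_max=1.0 / p_prior,
        prior_se=se_prior,
        posterior_se=se_post,
        n_prior=n_prior,
        n_posterior=n_post,
        prior_prob_analytic=analytic,
    )


@dataclass
class BetaPrevalenceInference:
    """Closed-form RB inference for a probability with a beta prior and
    binomial data (the prevalence analysis)."""

    alpha1: float
    alpha2: float
    n_pos: int
    n_neg: int
    estimate: float
    plausible_interval: tuple[float, float]
    plausible_content: float

    @property
    def posterior(self) -> tuple[float, float]:
        return (self.alpha1 + self.n_pos, self.alpha2 + self.n_neg)


def beta_binomial_rb(
    alpha1: float, alpha2: float, n_pos: int, n_neg: int
) -> BetaPrevalenceInference:
    """Exact relative belief inference for a binomial proportion ``w``.

    With prior ``beta(alpha1, alpha2)`` and data ``n_pos`` successes out of
    ``n_pos + n_neg``, the RB ratio is proportional to the likelihood
    ``w^n_pos (1-w)^n_neg``, so the RB estimate is the MLE and the plausible
    region ``{w : RB(w) > 1}`` is an interval found by root finding on the
    log density ratio; its posterior content comes from the beta cdf.
    """
    if min(alpha1, alpha2) <= 0:
        raise ValueError("beta parameters must be positive")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be nonnegative")
    b1, b2 = alpha1 + n_pos, alpha2 + n_neg
    const = special.betaln(alpha1, alpha2) - special.betaln(b1, b2)

    def log_rb(w):
        return const + n_pos * math.log(w) + n_neg * math.log1p(-w)

    if n_pos + n_neg == 0:
        # no data: RB identically 1, no evidence either way
        return BetaPrevalenceInference(
            alpha1, alpha2, n_pos, n_neg, math.nan, (math.nan, math.nan), 0.0
        )
    mle = n_pos / (n_pos + n_neg)
    eps = 1e-12
    # the log RB is strictly concave with its maximum at the MLE, so the
    # plausible region is the interval between the (at most two) roots
    peak = min(max(mle, eps), 1 - eps)
    lo = eps if log_rb(eps) >= 0 else optimize.brentq(log_rb, eps, peak)
    hi = (1 - eps if log_rb(1 - eps) >= 0
          else optimize.brentq(log_rb, peak, 1 - eps))
    content = float(stats.beta.cdf(hi, b1, b2) - stats.beta.cdf(lo, b1, b2))
    return BetaPrevalenceInference(
        alpha1=alpha1,
        alpha2=alpha2,
        n_pos=n_pos,
        n_neg=n_neg,
        estimate=mle,
        plausible_interval=(float(lo), float(hi)),
        plausible_content=content,
    )
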