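"""Prior elicitation from virtual-certainty statements.

Three hyperparameter families are elicited here:

* a ``beta(1 + tau*xi, 1 + tau*(1-xi))`` prior for the disease prevalence
  ``w``, parameterized by its mode ``xi`` and a concentration ``tau`` chosen
  as the smallest value putting probability ``gamma`` (virtual certainty,
  default 0.99) on a stated interval ``[l, u]``;
* a normal-gamma prior for a normal mean/precision pair, from an interval
  believed to contain the mean and bounds on the half-length of the
  virtual-certainty interval for an observation;
* the concentration parameter ``a`` of a Dirichlet process, from a bound on
  the prior probability that the random distribution differs from its base
  by at least ``epsilon`` on some event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PrevalencePrior",
    "NormalGammaParams",
    "DPConcentration",
    "elicit_beta_prevalence",
    "elicit_normal_gamma",
    "dp_discrepancy_bound",
    "elicit_dp_concentration",
    "VIRTUAL_CERTAINTY",
]

#: default virtual-certainty coverage
VIRTUAL_CERTAINTY = 0.99

_TAU_MAX = 1e7


@dataclass
class PrevalencePrior:
    """Elicited ``beta(1 + tau*xi, 1 + tau*(1-xi))`` prior for a prevalence.

    ``tau = 0`` is the uniform prior; ``tau = inf`` (``degenerate=True``)
    marks a point mass at ``xi`` (the known-prevalence case ``l = u``).
    """

    xi: float
    tau: float
    l: float
    u: float
    gamma: float
    degenerate: bool = False

    @property
    def alpha1(self) -> float:
        return 1.0 + self.tau * self.xi

    @property
    def alpha2(self) -> float:
        return 1.0 + self.tau * (1.0 - self.xi)

    def coverage(self, l: float | None = None, u: float | None = None) -> float:
        """Prior probability of ``[l, u]`` (defaults to the elicited interval)."""
        l = self.l if l is None else l
        u = self.u if u is None else u
        if self.degenerate:
            return float(l <= self.xi <= u)
        return float(
            stats.beta.cdf(u, self.alpha1, self.alpha2)
            - stats.beta.cdf(l, self.alpha1, self.alpha2)
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.degenerate:
            return np.full(n, self.xi)
        return rng.beta(self.alpha1, self.alpha2, n)

    def updated(self, n_pos: int, n_neg: int) -> tuple[float, float]:
        """Posterior beta parameters after binomial data."""
        if self.degenerate:
            raise ValueError("degenerate (known-prevalence) prior has no update")
        return (self.alpha1 + n_pos, self.alpha2 + n_neg)


def elicit_beta_prevalence(
    l: float,
    u: float,
    gamma: float = VIRTUAL_CERTAINTY,
    xi: float | None = None,
    tol: float = 1e-6,
) -> PrevalencePrior:
    """Smallest concentration ``tau`` with beta content of ``[l, u]`` >= gamma.

    ``xi`` defaults to the interval midpoint.  ``l == u`` encodes a known
    prevalence and returns the degenerate point-mass marker; ``[l, u] =
    [0, 1]`` is always covered, giving the uniform prior ``tau = 0``.
    Coverage is monotone increasing in ``tau`` (for ``xi`` inside ``[l,u]``),
    so bisection applies.
    """
    if not (0.0 <= l <= u <= 1.0):
        raise ValueError("need 0 <= l <= u <= 1")
    if not (0.0 < gamma <= 1.0):
        raise ValueError("gamma must be in (0, 1]")
    if xi is None:
        xi = (l + u) / 2.0
    if not (l <= xi <= u):
        raise ValueError("mode xi must lie inside [l, u]")
    if l == u:
        return PrevalencePrior(xi=xi, tau=math.inf, l=l, u=u, gamma=gamma,
                               degenerate=True)

    def coverage(tau: float) -> float:
        a1, a2 = 1.0 + tau * xi, 1.0 + tau * (1.0 - xi)
        return stats.beta.cdf(u, a1, a2) - stats.beta.cdf(l, a1, a2)

    if coverage(0.0) >= gamma:
        return PrevalencePrior(xi=xi, tau=0.0, l=l, u=u, gamma=gamma)
    if coverage(_TAU_MAX) < gamma:
        raise ValueError("requested coverage unattainable (interior mode?)")
    tau = optimize.brentq(lambda t: coverage(t) - gamma, 0.0, _TAU_MAX,
                          xtol=tol, rtol=4 * np.finfo(float).eps)
    while coverage(tau) < gamma:  # land on the >= gamma side of the root
        tau += tol
    return PrevalencePrior(xi=xi, tau=float(tau), l=l, u=u, gamma=gamma)


@dataclass
class NormalGammaParams:
    """Normal-gamma hyperparameters: ``mu | sigma^2 ~ N(mu0, tau0^2 sigma^2)``
    and ``1/sigma^2 ~ gamma(lambda1, rate=lambda2)``.

    Optional elicitation metadata records the virtual-certainty inputs:
    ``(m1, m2)`` bound the mean, ``(l0, u0)`` bound the half-length of the
    observation interval.
    """

    mu0: float
    tau0: float
    lambda1: float
    lambda2: float
    m1: float | None = None
    m2: float | None = None
    l0: float | None = None
    u0: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("gamma shape and rate must be positive")

    def sigma_coverage(self) -> float:
        """Prior probability that sigma lies in (l0/z, u0/z), z the
        (1+gamma)/2 normal quantile; defined only for elicited priors."""
        if self.l0 is None:
            raise ValueError("no elicitation inputs stored")
        z = stats.norm.ppf((1 + self.gamma) / 2)
        hi = z**2 / self.l0**2
        lo = z**2 / self.u0**2
        g = stats.gamma(self.lambda1, scale=1.0 / self.lambda2)
        return float(g.cdf(hi) - g.cdf(lo))

    def sample_base(self, n: int, rng: np.random.Generator):
        """Draw ``(mu, sigma^2)`` pairs from the prior."""
        inv_s2 = rng.gamma(self.lambda1, 1.0 / self.lambda2, n)
        s2 = 1.0 / inv_s2
        mu = rng.normal(self.mu0, self.tau0 * np.sqrt(s2))
        return mu, s2


def elicit_normal_gamma(
    m1: float,
    m2: float,
    l0: float,
    u0: float,
    gamma: float = VIRTUAL_CERTAINTY,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> NormalGammaParams:
    """Elicit ``(mu0, tau0, lambda1, lambda2)`` from virtual-certainty bounds.

    ``mu0`` is the midpoint of ``(m1, m2)`` and ``tau0 = (m2-m1)/(2 u0)``.
    ``(lambda1, lambda2)`` are found by alternating between the two coverage
    equations for the precision: fix ``lambda1`` and solve
    ``G(z^2/l0^2; lambda1, lambda2) = (1+gamma)/2`` for ``lambda2`` (a
    quantile evaluation), then solve
    ``G(z^2/u0^2; lambda1, lambda2) = (1-gamma)/2`` for ``lambda1``, until
    the coverage of ``(l0/z, u0/z)`` for sigma is within ``tol`` of gamma.
    """
    if not m1 < m2:
        raise ValueError("need m1 < m2")
    if not 0 < l0 < u0:
        raise ValueError("need 0 < l0 < u0")
    if not 0 < gamma < 1:
        raise ValueError("gamma must be in (0, 1)")
    z = stats.norm.ppf((1 + gamma) / 2)
    x_hi = z**2 / l0**2  # upper precision bound
    x_lo = z**2 / u0**2  # lower precision bound
    p_hi = (1 + gamma) / 2
    p_lo = (1 - gamma) / 2

    lam1 = 1.0
    lam2 = stats.gamma.ppf(p_hi, lam1) / x_hi
    last = (lam1, lam2)
    for _ in range(max_iter):
        lam2 = stats.gamma.ppf(p_hi, lam1) / x_hi

        def f(l1: float) -> float:
            return stats.gamma.cdf(x_lo * lam2, l1) - p_lo

        lam1 = optimize.brentq(f, 1e-8, 1e8)
        cov = stats.gamma.cdf(x_hi * lam2, lam1) - stats.gamma.cdf(x_lo * lam2, lam1)
        last = (lam1, lam2)
        if abs(cov - gamma) < tol:
            break
    else:
        raise RuntimeError(
            f"elicitation did not converge after {max_iter} iterations; "
            f"last iterate (lambda1, lambda2) = {last}"
        )
    return NormalGammaParams(
        mu0=(m1 + m2) / 2.0,
        tau0=(m2 - m1) / (2.0 * u0),
        lambda1=float(lam1),
        lambda2=float(lam2),
        m1=m1, m2=m2, l0=l0, u0=u0, gamma=gamma,
    )


@dataclass
class DPConcentration:
    """Elicited Dirichlet-process concentration.

    ``bound`` is the achieved supremum of the prior probability that the
    random distribution differs from the base by at least ``epsilon`` on
    some event.
    """

    a: float
    epsilon: float
    bound: float


def dp_discrepancy_bound(a: float, epsilon: float, grid: int = 2001) -> float:
    """Sup over ``r`` of ``1 - Beta([max(0,r-eps), min(1,r+eps)]; ar, a(1-r))``.

    This bounds the prior probability that ``F ~ DP(a, H)`` differs from
    ``H`` by at least ``epsilon`` on some event.  At ``r`` in ``{0, 1}`` the
    beta degenerates to a point mass inside the window, contributing 0, so
    the supremum is taken over the open interval (dense grid plus bounded
    local refinement).
    """
    if a <= 0:
        raise ValueError("concentration must be positive")
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must be in (0, 1]")
    if epsilon >= 1.0:
        return 0.0

    def neg_window(r: float | np.ndarray) -> np.ndarray:
        lo = np.maximum(0.0, np.asarray(r) - epsilon)
        hi = np.minimum(1.0, np.asarray(r) + epsilon)
        return 1.0 - (
            stats.beta.cdf(hi, a * r, a * (1.0 - r))
            - stats.beta.cdf(lo, a * r, a * (1.0 - r))
        )

    r = np.linspace(0.0, 1.0, grid)[1:-1]
    vals = neg_window(r)
    i = int(np.argmax(vals))
    lo_r, hi_r = r[max(i - 1, 0)], r[min(i + 1, r.size - 1)]
    res = optimize.minimize_scalar(
        lambda x: -neg_window(x), bounds=(lo_r, hi_r), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(max(vals[i], -res.fun))


def elicit_dp_concentration(
    epsilon: float, target: float, resolution: float = 0.1
) -> DPConcentration:
    """Smallest concentration (on a ``resolution`` grid) whose discrepancy
    bound at radius ``epsilon`` is at most ``target``.

    The bound is nonincreasing in ``a``, so the root is bracketed by
    doubling and refined by bisection, then rounded up to the grid.
    """
    if not 0 < target < 1:
        raise ValueError("target must be in (0, 1)")
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must be in (0, 1)")
    lo, hi = resolution, resolution
    while dp_discrepancy_bound(hi, epsilon) > target:
        lo, hi = hi, hi * 2.0
        if hi > 1e7:
            raise RuntimeError("no concentration below 1e7 meets the target")
    if hi == resolution:
        a = resolution
    else:
        root = optimize.brentq(
            lambda a: dp_discrepancy_bound(a, epsilon) - target, lo, hi,
            xtol=1e-4,
        )
        a = math.ceil(root / resolution - 1e-9) * resolution
    return DPConcentration(a=float(a), epsilon=epsilon,
                           bound=dp_discrepancy_bound(a, epsilon))
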