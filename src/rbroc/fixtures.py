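"""Deterministic data generators and closed-form benchmark models.

The Lehmann (proportional-hazards) family ``F_D = F_ND^q`` admits closed
forms for the AUC and the optimal cutoff, which makes it the standard
benchmark for exercising the error-characteristic machinery: the AUC is
``1 - 1/(q+1)`` regardless of the base distribution, and a finite
Error-minimizing cutoff exists only when ``q > (1-w)/w`` — a sharp
illustration that a near-perfect AUC does not guarantee a usable
classifier at small prevalence.

The module also bundles the worked-example inputs used throughout the
documentation and tests (simulated multinomial counts and normal summary
statistics, stored verbatim), plus seeded generators for fresh synthetic
datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .binormal import BinormalParams, SummaryStats
from .discrete import ProbPair
from .errors import ErrorProfile, error_profile

__all__ = [
    "LehmannModel",
    "LehmannQuantities",
    "lehmann_quantities",
    "generate_discrete_dataset",
    "generate_binormal_dataset",
    "demo_discrete_counts",
    "demo_discrete_truth",
    "demo_binormal_summaries",
    "demo_binormal_dataset",
]


@dataclass(frozen=True)
class LehmannModel:
    """``F_D = F_ND^q`` with a continuous strictly increasing base cdf.

    ``q > 1`` iff AUC > 1/2; the base cdf never enters the closed forms,
    only the value ``F_ND(copt)`` does.
    """

    q: float
    w: float

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError("power q must be positive")
        if not 0.0 < self.w < 1.0:
            raise ValueError("prevalence must be strictly inside (0, 1)")


@dataclass(frozen=True)
class LehmannQuantities:
    auc: float
    exists: bool
    fnd_at_copt: float | None  # F_ND(copt); None when copt is infinite
    profile: ErrorProfile | None


def lehmann_quantities(model: LehmannModel) -> LehmannQuantities:
    """Closed-form AUC, optimal-cutoff location and error profile.

    ``AUC = 1 - 1/(q+1)``.  A finite cutoff exists iff ``q > (1-w)/w``,
    in which case ``F_ND(copt) = ((1-w)/(q w))^(1/(q-1))`` and the error
    profile follows from ``FNR = F_ND(copt)^q``, ``FPR = 1 - F_ND(copt)``.
    At or below the boundary the optimal rule classifies everyone as
    nondiseased.
    """
    q, w = model.q, model.w
    auc = 1.0 - 1.0 / (q + 1.0)
    if q <= (1.0 - w) / w or math.isclose(q, 1.0):
        return LehmannQuantities(auc=auc, exists=False, fnd_at_copt=None,
                                 profile=None)
    fnd = ((1.0 - w) / (q * w)) ** (1.0 / (q - 1.0))
    fnr = fnd**q
    fpr = 1.0 - fnd
    return LehmannQuantities(
        auc=auc, exists=True, fnd_at_copt=float(fnd),
        profile=error_profile(fnr, fpr, w),
    )


def generate_discrete_dataset(
    p_nd, p_d, n_nd: int, n_d: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial category counts for the two groups."""
    pair = ProbPair(p_nd, p_d)  # validates
    rng = np.random.default_rng(seed)
    f_nd = rng.multinomial(n_nd, pair.p_nd)
    f_d = rng.multinomial(n_d, pair.p_d)
    return f_nd, f_d


def generate_binormal_dataset(
    params: BinormalParams, n_nd: int, n_d: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, SummaryStats, SummaryStats]:
    """Normal samples for the two groups plus their summary statistics."""
    rng = np.random.default_rng(seed)
    x_nd = rng.normal(params.mu_nd, math.sqrt(params.sigma2_nd), n_nd)
    x_d = rng.normal(params.mu_d, math.sqrt(params.sigma2_d), n_d)
    return (x_nd, x_d, SummaryStats.from_data(x_nd),
            SummaryStats.from_data(x_d))


def demo_discrete_counts() -> tuple[np.ndarray, np.ndarray]:
    """Bundled 5-category counts: 50 nondiseased draws from
    (0.5, 0.2, 0.1, 0.1, 0.1) and 100 diseased draws from
    (0.1, 0.1, 0.2, 0.3, 0.3), stored verbatim."""
    return (np.array([29, 7, 4, 5, 5]), np.array([14, 7, 25, 33, 21]))


def demo_discrete_truth() -> ProbPair:
    """The generating category probabilities behind the bundled counts."""
    return ProbPair(np.array([0.5, 0.2, 0.1, 0.1, 0.1]),
                    np.array([0.1, 0.1, 0.2, 0.3, 0.3]))


def demo_binormal_summaries() -> tuple[SummaryStats, SummaryStats]:
    """Bundled normal summary statistics: 25 nondiseased N(0,1) draws and
    20 diseased N(1,1) draws, stored verbatim as (n, mean, ss)."""
    return (SummaryStats(25, -0.072, 19.638), SummaryStats(20, 0.976, 16.778))


def demo_binormal_dataset(seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic reconstruction of the raw samples behind
    :func:`demo_binormal_summaries`: normal draws affinely rescaled so the
    sample mean and sum of squared deviations match the bundled summaries
    exactly.  The original observations were never recorded, so this is a
    moment-matched stand-in, adequate wherever only the empirical
    distribution's location/spread matter."""
    s_nd, s_d = demo_binormal_summaries()
    rng = np.random.default_rng(seed)
    out = []
    for s, mu in ((s_nd, 0.0), (s_d, 1.0)):
        x = rng.normal(mu, 1.0, s.n)
        x = (x - x.mean()) / math.sqrt(np.sum((x - x.mean()) ** 2))
        out.append(x * math.sqrt(s.ss) + s.mean)
    return out[0], out[1]
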