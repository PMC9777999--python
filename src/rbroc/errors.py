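"""Prevalence-dependent error characteristics of a classifier (X, c).

A subject is called positive when its diagnostic value exceeds the cutoff.
Conditional rates (FNR, FPR and their complements TPR, TNR) do not involve
the prevalence ``w``; the population-level quantities do:

    Error(c) = w FNR(c) + (1-w) FPR(c)
    FDR(c)   = (1-w) FPR(c) / [w (1-FNR(c)) + (1-w) FPR(c)]
    FNDR(c)  = w FNR(c) / [w FNR(c) + (1-w) (1-FPR(c))]
    PPV(c)   = 1 - FDR(c),   NPV(c) = 1 - FNDR(c)

Small prevalence inflates FDR even when both conditional error rates are
small (the base-rate fallacy), which is why a classifier cannot be judged
from its conditional rates alone.

Ratios with zero denominator (no positive or no negative calls) are
reported as ``nan`` — an "undefined" marker rather than an exception — so
downstream summaries can drop them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ErrorProfile",
    "error_profile",
    "weighted_error_cutoff",
    "closest_to_01_cutoff",
]


@dataclass(frozen=True)
class ErrorProfile:
    """All error characteristics of a classifier at one cutoff."""

    fnr: float
    fpr: float
    w: float
    tpr: float
    tnr: float
    error: float
    fdr: float
    fndr: float
    ppv: float
    npv: float

    def as_dict(self) -> dict[str, float]:
        return {
            "fnr": self.fnr, "fpr": self.fpr, "tpr": self.tpr,
            "tnr": self.tnr, "w": self.w, "error": self.error,
            "fdr": self.fdr, "fndr": self.fndr, "ppv": self.ppv,
            "npv": self.npv,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def error_profile(fnr: float, fpr: float, w: float) -> ErrorProfile:
    """Evaluate every error characteristic at given conditional rates and
    prevalence.  All three arguments must be probabilities."""
    for name, v in (("fnr", fnr), ("fpr", fpr), ("w", w)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v!r}")
    tpr, tnr = 1.0 - fnr, 1.0 - fpr
    pos_call = w * tpr + (1.0 - w) * fpr  # P(classified positive)
    neg_call = w * fnr + (1.0 - w) * tnr
    fdr = _ratio((1.0 - w) * fpr, pos_call)
    fndr = _ratio(w * fnr, neg_call)
    return ErrorProfile(
        fnr=fnr, fpr=fpr, w=w, tpr=tpr, tnr=tnr,
        error=w * fnr + (1.0 - w) * fpr,
        fdr=fdr,
        fndr=fndr,
        ppv=1.0 - fdr if not math.isnan(fdr) else math.nan,
        npv=1.0 - fndr if not math.isnan(fndr) else math.nan,
    )


def _validate_rates(cutoffs, fnr, fpr):
    c = np.asarray(cutoffs, dtype=float)
    fn = np.asarray(fnr, dtype=float)
    fp = np.asarray(fpr, dtype=float)
    if c.size == 0:
        raise ValueError("empty candidate cutoff set")
    if not (c.shape == fn.shape == fp.shape):
        raise ValueError("cutoffs, fnr and fpr must have equal lengths")
    return c, fn, fp


def weighted_error_cutoff(cutoffs, fnr, fpr, w0: float) -> float:
    """Cutoff minimizing ``w0 FNR + (1-w0) FPR`` over a finite candidate set.

    ``w0 = 1/2`` recovers the Youden-index maximizer (Youden's J =
    1 - 2 * Error at w = 1/2).  Ties break to the smallest cutoff.
    """
    if not 0.0 <= w0 <= 1.0:
        raise ValueError("w0 must be in [0, 1]")
    c, fn, fp = _validate_rates(cutoffs, fnr, fpr)
    order = np.argsort(c, kind="stable")
    obj = w0 * fn[order] + (1.0 - w0) * fp[order]
    return float(c[order][int(np.argmin(obj))])


def closest_to_01_cutoff(cutoffs, fnr, fpr) -> float:
    """Cutoff minimizing the squared ROC-space distance to the perfect
    classifier point (0, 1): ``FPR^2 + FNR^2``.  Ties break to the smallest
    cutoff."""
    c, fn, fp = _validate_rates(cutoffs, fnr, fpr)
    order = np.argsort(c, kind="stable")
    obj = fp[order] ** 2 + fn[order] ** 2
    return float(c[order][int(np.argmin(obj))])
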