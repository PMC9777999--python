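"""Report serialization: dataclass reports to JSON-safe dicts and short
human-readable summaries."""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Any

import numpy as np

__all__ = ["to_jsonable", "dumps", "text_summary"]

_SKIP_FIELDS = {"prior", "posterior", "summary"}  # bulky nested histograms


def to_jsonable(obj: Any, keep_histograms: bool = True) -> Any:
    """Recursively convert reports (dataclasses, arrays, numpy scalars) to
    JSON-serializable structures; non-finite floats become strings."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {}
        for f in dataclasses.fields(obj):
            if not keep_histograms and f.name in _SKIP_FIELDS:
                continue
            out[f.name] = to_jsonable(getattr(obj, f.name), keep_histograms)
        return out
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v, keep_histograms) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v, keep_histograms) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v, keep_histograms) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if math.isnan(v):
            return "undefined"
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        return v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def dumps(report: Any, keep_histograms: bool = True) -> str:
    """Deterministic JSON encoding of a report (sorted keys, fixed
    separators): identical seeds give byte-identical output."""
    return json.dumps(to_jsonable(report, keep_histograms), sort_keys=True,
                      indent=2)


def _fmt(v: float) -> str:
    if isinstance(v, str):
        return v
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "undefined"
    return f"{v:.3f}"


def text_summary(report: Any) -> str:
    """Compact plain-text account of the inferential sequence."""
    lines = []
    h0 = report.h0
    lines.append(
        f"H0 assessment: RB = {h0.rb:.3f} ({h0.direction}), "
        f"strength = {h0.strength:.3f} "
        f"[prior prob {h0.prior_prob:.3f}"
        + (" (analytic)" if h0.prior_prob_analytic else
           f" +/- {h0.prior_se:.4f}")
        + f", posterior prob {h0.posterior_prob:.3f}]"
    )
    lines.append(f"conditioned on the hypothesis: {report.conditioned}")
    auc = report.auc
    lo, hi = auc.plausible_region
    lines.append(
        f"AUC estimate {auc.estimate:.3f}, plausible region "
        f"[{_fmt(lo)}, {_fmt(hi)}] with posterior content "
        f"{auc.plausible_content:.3f}"
    )
    cut = getattr(report, "cutoff", None)
    if cut is not None:
        lo, hi = cut.plausible_interval
        lines.append(
            f"cutoff estimate {_fmt(cut.estimate)} (cmod "
            f"{cut.estimate_cmod:.3f}), plausible interval "
            f"({_fmt(lo)}, {_fmt(hi)}) with posterior content "
            f"{cut.plausible_content:.3f}"
        )
    cd = getattr(report, "copt", None)
    if cd is not None:
        vals = ", ".join(f"{v:g}" for v in cd.plausible_set)
        lines.append(
            f"cutoff estimate {cd.estimate:g}, plausible set {{{vals}}} "
            f"with posterior content {cd.plausible_content:.3f}"
        )
    if report.error_characteristics:
        ests = ", ".join(
            f"{name.upper()} {_fmt(r.estimate)}"
            for name, r in report.error_characteristics.items()
        )
        lines.append(f"error characteristics at the estimated cutoff: {ests}")
    if report.prevalence is not None:
        p = report.prevalence
        lo, hi = p.plausible_interval
        lines.append(
            f"prevalence estimate {p.estimate:.3f}, plausible interval "
            f"({lo:.3f}, {hi:.3f}) with posterior content "
            f"{p.plausible_content:.3f}"
        )
    else:
        lines.append(f"prevalence handling: {report.prevalence_mode}")
    return "\n".join(lines)
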