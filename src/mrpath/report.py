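"""Human-readable report tables (3-decimal effects, 2-significant p-values).

The report layer rounds for display only; full-precision values travel in
the machine-readable JSON written alongside every bundle.  OR columns are
recomputed from the beta-scale entries at format time, so every emitted
row satisfies OR = exp(beta) and CI_OR = exp(CI_beta) to formatting
precision.
"""

from __future__ import annotations

import json
import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .mediation import MediationResult
from .mvmr import MVMREstimate, MVMRSet
from .uni_mr import MREstimate

METHOD_LABELS = {
    "wald": "Wald ratio",
    "ivw_fe": "Inverse variance weighted (fixed effects)",
    "ivw_re": "Inverse variance weighted",
    "egger": "MR Egger",
    "egger_simex": "MR Egger (SIMEX)",
    "weighted_median": "Weighted median",
    "presso_corrected": "MR-PRESSO outlier-corrected",
    "mvmr_ivw": "IVW",
    "mvmr_egger": "MR Egger",
}


def format_p(p: float) -> str:
    if p >= 0.001:
        return f"{p:.3f}"
    return f"{p:.2E}"


def _round3(x: float) -> float:
    return float(f"{x:.3f}")


def estimates_table(
    estimates: Iterable[MREstimate],
    outcome: str,
    binary_outcome: bool = True,
) -> pd.DataFrame:
    """One row per method, in the shape of a published univariable MR table."""
    rows = []
    for est in estimates:
        row = {
            "Outcome": outcome,
            "Method": METHOD_LABELS.get(est.method, est.method),
            "SNPs": est.n_snps,
            "Beta": _round3(est.beta),
            "SE": _round3(est.se),
            "Lower CI": _round3(est.ci_low),
            "Upper CI": _round3(est.ci_high),
        }
        if binary_outcome:
            row["OR"] = _round3(math.exp(est.beta))
            row["OR Lower CI"] = _round3(math.exp(est.ci_low))
            row["OR Upper CI"] = _round3(math.exp(est.ci_high))
        row["p-value"] = format_p(est.pval)
        rows.append(row)
    return pd.DataFrame(rows)


def mvmr_table(
    mv_set: MVMRSet,
    ivw_fit: MVMREstimate,
    egger_fit: Optional[MVMREstimate] = None,
) -> pd.DataFrame:
    """Per-exposure direct effects (IVW and, when available, Egger)."""
    rows = []
    for name in mv_set.exposures:
        est = ivw_fit.estimates[name]
        row = {
            "Exposure": name,
            "Total SNPs": mv_set.L,
            "IVW OR": _round3(math.exp(est.beta)),
            "IVW Lower CI": _round3(math.exp(est.ci_low)),
            "IVW Upper CI": _round3(math.exp(est.ci_high)),
            "IVW p-value": format_p(est.pval),
        }
        if egger_fit is not None:
            e = egger_fit.estimates[name]
            row.update(
                {
                    "Egger OR": _round3(math.exp(e.beta)),
                    "Egger Lower CI": _round3(math.exp(e.ci_low)),
                    "Egger Upper CI": _round3(math.exp(e.ci_high)),
                    "Egger p-value": format_p(e.pval),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def mediation_table(results: Iterable[MediationResult]) -> pd.DataFrame:
    """Total / direct a / direct b / indirect / proportion, one mediator per row."""
    rows = []
    for r in results:
        rows.append(
            {
                "Mediator": r.mediator,
                "Total effect": _round3(r.total.beta),
                "Direct effect a": _round3(r.a),
                "Direct effect b": _round3(r.b),
                "Indirect effect": _round3(r.indirect),
                "95% CI": f"({_round3(r.ci_low):.3f}, {_round3(r.ci_high):.3f})",
                "Mediation proportion": f"{r.proportion_pct:.2f}%",
            }
        )
    return pd.DataFrame(rows)


def estimate_to_dict(est: MREstimate) -> dict:
    return {
        "method": est.method,
        "n_snps": est.n_snps,
        "beta": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pval": est.pval,
        "or": float(np.exp(est.beta)),
        "or_ci_low": float(np.exp(est.ci_low)),
        "or_ci_high": float(np.exp(est.ci_high)),
    }


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(o)}")
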