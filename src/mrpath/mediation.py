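"""Two-step MR mediation with product-of-coefficients indirect effects.

Step 1 estimates the exposure's causal effect on each candidate mediator
by univariable IVW (full instrument pipeline).  Step 2, run only for
mediators passing the step-1 significance gate, estimates each mediator's
effect on the outcome conditioning on the exposure (and the other gated
mediators) by multivariable IVW.  The indirect effect is the product
a * b with a first-order delta-method standard error,

    se(ab) = sqrt(a^2 se_b^2 + b^2 se_a^2),

and the mediation proportion is indirect / total, where the total effect
comes from the univariable exposure-to-outcome analysis on the same
instrument set (it is not re-derived as direct + indirect).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .instruments import (
    HarmonizationError,
    SelectionConfig,
    f_filter,
    harmonize,
    ld_clump,
    select_instruments,
    steiger_filter,
)
from .mvmr import assemble_mvmr, mvmr_ivw
from .sumstats import LDReference, SumStatTable
from .uni_mr import MREstimate, ivw

Z975 = stats.norm.ppf(0.975)


@dataclass
class IndirectEffect:
    """Product-of-coefficients indirect effect with delta-method CI."""

    indirect: float
    se: float
    ci_low: float
    ci_high: float


@dataclass
class MediationResult:
    """Total / direct-a / direct-b / indirect decomposition for one mediator."""

    mediator: str
    total: MREstimate            # exposure -> outcome (c)
    a: float                     # exposure -> mediator
    se_a: float
    a_pval: float
    b: float                     # mediator -> outcome | exposure
    se_b: float
    b_pval: float
    indirect: float              # a * b
    se_indirect: float
    ci_low: float
    ci_high: float
    proportion_pct: float        # 100 * indirect / total
    inconsistent: bool           # indirect and total of opposite sign
    c_prime: Optional[float] = None     # exposure direct effect from step 2
    se_c_prime: Optional[float] = None


def indirect_effect(a: float, se_a: float, b: float, se_b: float) -> IndirectEffect:
    """Product of coefficients with first-order delta-method SE and 95% CI."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    ab = a * b
    se = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))
    return IndirectEffect(ab, se, ab - Z975 * se, ab + Z975 * se)


def mediation_proportion(indirect: float, total: float) -> tuple[float, bool]:
    """Mediation proportion as a percent, with an inconsistency flag.

    Returns (100 * indirect / total, flag); the flag is True when the
    indirect and total effects have opposite signs ("inconsistent
    mediation"), in which case the percentage is not interpretable as a
    share of the total effect.
    """
    if total == 0:
        raise ValueError("mediation proportion undefined for a zero total effect")
    pct = 100.0 * indirect / total
    return pct, (indirect * total < 0)


def _instrument_pipeline(
    exposure: SumStatTable,
    outcome: SumStatTable,
    ld: LDReference,
    cfg: SelectionConfig,
    n_exp: Optional[int],
    n_out: Optional[int],
):
    """Select + clump + harmonize + F filter + Steiger filter."""
    iv = ld_clump(select_instruments(exposure, cfg), ld, cfg)
    h = harmonize(iv, outcome, cfg, ld=ld)
    h, _ = f_filter(h, cfg)
    if n_exp is not None and n_out is not None:
        h, _ = steiger_filter(
            h, n_exp, n_out,
            exposure_type=exposure.trait_type,
            outcome_type=outcome.trait_type,
        )
    return h


def _table_n(table: SumStatTable) -> Optional[int]:
    n = table.data["n"].dropna()
    return int(n.iloc[0]) if len(n) else None


def two_step_mediation(
    exposure: SumStatTable,
    mediators: Sequence[SumStatTable],
    outcome: SumStatTable,
    ld: LDReference,
    cfg: Optional[SelectionConfig] = None,
    seed: Optional[int] = None,
) -> tuple[list[MediationResult], str]:
    """Run the two-step mediation analysis.

    Returns (results, status).  ``results`` holds one entry per mediator
    whose step-1 exposure-to-mediator IVW effect is significant at
    ``cfg.alpha``; when no mediator passes the gate the list is empty and
    the status is ``"no mediation pathway"`` (a valid scientific outcome,
    not a failure).  ``seed`` is accepted for interface symmetry with the
    stochastic stages; the estimators used here are deterministic.
    """
    cfg = cfg or SelectionConfig()
    n_exp = _table_n(exposure)
    n_out = _table_n(outcome)

    # total effect: univariable exposure -> outcome on the full pipeline
    h_total = _instrument_pipeline(exposure, outcome, ld, cfg, n_exp, n_out)
    total = ivw(h_total)

    # step 1: exposure -> each mediator
    step1 = {}
    for med in mediators:
        try:
            h_med = _instrument_pipeline(
                exposure, med, ld, cfg, n_exp, _table_n(med)
            )
        except HarmonizationError:
            continue
        step1[med.trait_name] = ivw(h_med)
    gated = [m for m in mediators
             if m.trait_name in step1 and step1[m.trait_name].pval < cfg.alpha]
    if not gated:
        return [], "no mediation pathway"

    # step 2: multivariable mediator -> outcome conditioning on exposure
    mv_set = assemble_mvmr([exposure, *gated], outcome, ld, cfg)
    mv = mvmr_ivw(mv_set)

    results = []
    for med in gated:
        name = med.trait_name
        if name not in mv.estimates:  # instrument-less after joint clumping
            continue
        a_est = step1[name]
        b_est = mv.estimates[name]
        ind = indirect_effect(a_est.beta, a_est.se, b_est.beta, b_est.se)
        pct, inconsistent = mediation_proportion(ind.indirect, total.beta)
        cprime_est = mv.estimates.get(exposure.trait_name)
        results.append(
            MediationResult(
                mediator=name,
                total=total,
                a=a_est.beta,
                se_a=a_est.se,
                a_pval=a_est.pval,
                b=b_est.beta,
                se_b=b_est.se,
                b_pval=b_est.pval,
                indirect=ind.indirect,
                se_indirect=ind.se,
                ci_low=ind.ci_low,
                ci_high=ind.ci_high,
                proportion_pct=pct,
                inconsistent=inconsistent,
                c_prime=cprime_est.beta if cprime_est else None,
                se_c_prime=cprime_est.se if cprime_est else None,
            )
        )
    status = "ok" if results else "no mediation pathway"
    return results, status
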