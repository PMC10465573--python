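"""MR-PRESSO: pleiotropy residual sum and outlier tests.

Three stages share one simulation pass:

* **global test** — the observed weighted residual sum of squares about
  leave-one-out IVW fits is compared with its Monte-Carlo null
  distribution (summary estimates resampled from their sampling
  distributions around the leave-one-out fitted values);
* **outlier test** — run when the global test is significant; per-SNP
  residual tail probabilities, Bonferroni-corrected across instruments;
* **distortion test** — percent change of the IVW estimate after outlier
  removal, referenced to the change produced by removing the same number
  of instruments uniformly at random.

Monte-Carlo p-values use the (1 + #exceedances) / (n_sim + 1) convention,
so they are never exactly zero and never exceed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .instruments import HarmonizedSet
from .uni_mr import EstimationError, MREstimate, ivw


@dataclass
class PressoResult:
    """Global / outlier / distortion outputs with the corrected estimate."""

    rss_obs: float
    global_p: float
    per_snp_p: np.ndarray
    outliers: list
    distortion_pct: Optional[float]
    distortion_p: Optional[float]
    corrected: MREstimate
    n_sim: int
    snp_ids: list = field(default_factory=list)


def _loo_slopes(bx, by, w):
    """Leave-one-out fixed-effect IVW slopes, vectorized over the last axis."""
    sxy = (w * bx * by).sum(axis=-1, keepdims=True)
    sxx = (w * bx * bx).sum(axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    outlier_alpha: float = 0.05,
    weighted: bool = True,
) -> PressoResult:
    """Run the full MR-PRESSO procedure on a harmonized set.

    ``weighted`` uses residual weights 1/se_out^2 (the default here); the
    unweighted variant is available behind the flag.  The outlier test is
    only consulted when the global test is significant at ``alpha``;
    per-SNP Bonferroni calls flag SNP j when p_j * L < ``outlier_alpha``.

    Raises when fewer than 4 instruments are supplied or when every
    instrument is flagged as an outlier.
    """
    L = len(h)
    if L < 4:
        raise EstimationError("MR-PRESSO needs at least four SNPs")
    if n_sim < 100:
        raise EstimationError("MR-PRESSO needs n_sim >= 100")
    rng = np.random.default_rng(seed)

    bx, by = h.beta_exp, h.beta_out
    w = 1.0 / h.se_out**2 if weighted else np.ones(L)

    theta_loo = np.asarray(_loo_slopes(bx, by, w)).reshape(L)
    d = by - theta_loo * bx
    d2w = d**2 * w
    rss_obs = float(d2w.sum())

    # Monte-Carlo null: resample summary estimates around the LOO fits
    bx_sim = bx + h.se_exp * rng.standard_normal((n_sim, L))
    by_sim = theta_loo * bx + h.se_out * rng.standard_normal((n_sim, L))
    theta_loo_sim = _loo_slopes(bx_sim, by_sim, w)
    d_sim = by_sim - theta_loo_sim * bx_sim
    d2w_sim = d_sim**2 * w
    rss_sim = d2w_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    per_snp_p = (1 + np.sum(d2w_sim >= d2w, axis=0)) / (n_sim + 1)

    outliers: list = []
    if global_p < alpha:
        flagged = per_snp_p * L < outlier_alpha
        outliers = [h.snp_ids[j] for j in np.flatnonzero(flagged)]
    if len(outliers) == L:
        raise EstimationError("no instruments remain after outlier removal")

    full = ivw(h)
    distortion_pct = distortion_p = None
    if outliers:
        keep = np.array([s not in set(outliers) for s in h.snp_ids])
        corrected = ivw(h.subset(keep))
        if corrected.beta != 0:
            distortion_pct = float(
                100.0 * (full.beta - corrected.beta) / corrected.beta
            )
            n_out = len(outliers)
            pct_null = np.empty(n_sim)
            sw = w
            sxx_all = float(np.sum(sw * bx * bx))
            sxy_all = float(np.sum(sw * bx * by))
            for k in range(n_sim):
                drop = rng.choice(L, size=n_out, replace=False)
                mask = np.ones(L, dtype=bool)
                mask[drop] = False
                sxx = float(np.sum(sw[mask] * bx[mask] ** 2))
                sxy = float(np.sum(sw[mask] * bx[mask] * by[mask]))
                theta_red = sxy / sxx
                pct_null[k] = 100.0 * (sxy_all / sxx_all - theta_red) / theta_red
            distortion_p = float(
                (1 + np.sum(np.abs(pct_null) >= abs(distortion_pct))) / (n_sim + 1)
            )
        corrected.method = "presso_corrected"
    else:
        corrected = MREstimate(
            method="presso_corrected",
            n_snps=full.n_snps,
            beta=full.beta,
            se=full.se,
            ci_low=full.ci_low,
            ci_high=full.ci_high,
            pval=full.pval,
            outcome_binary=full.outcome_binary,
        )

    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        per_snp_p=per_snp_p,
        outliers=outliers,
        distortion_pct=distortion_pct,
        distortion_p=distortion_p,
        corrected=corrected,
        n_sim=n_sim,
        snp_ids=list(h.snp_ids),
    )


def presso_report(before: MREstimate, result: PressoResult) -> dict:
    """Before/after comparison row in the shape of a published outlier note.

    Emits the pre- and post-correction estimates (beta and OR scales),
    the removed SNP ids, and the distortion p, e.g. "identified two
    outliers; the causal estimate was not significantly changed".
    """
    after = result.corrected
    return {
        "beta_before": before.beta,
        "beta_after": after.beta,
        "or_before": before.or_scale[0],
        "or_after": after.or_scale[0],
        "n_snps_before": before.n_snps,
        "n_snps_after": after.n_snps,
        "outliers": list(result.outliers),
        "global_p": result.global_p,
        "distortion_pct": result.distortion_pct,
        "distortion_p": result.distortion_p,
    }
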