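"""Multivariable two-sample MR.

Assembles a joint instrument set across several exposures (union of each
exposure's genome-wide-significant variants, jointly clumped with the
minimum p across exposures as the ranking key, every exposure's effect
extracted for every surviving variant and harmonized to a common effect
allele and to the outcome), then estimates each exposure's direct effect
on the outcome conditioning on the others by weighted least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import (
    HarmonizationError,
    SelectionConfig,
    _align_alleles,
    ld_clump,
    select_instruments,
)
from .sumstats import LDReference, SumStatTable
from .uni_mr import EstimationError, MREstimate, _estimate


@dataclass
class MVMRSet:
    """Joint instrument matrix: L SNPs by K exposures, plus outcome vectors."""

    exposures: list            # exposure names, length K
    snp_ids: list              # length L
    beta_exp: np.ndarray       # L x K
    se_exp: np.ndarray         # L x K
    beta_out: np.ndarray       # length L
    se_out: np.ndarray
    outcome_name: str = "outcome"
    outcome_binary: bool = True
    instrumentless: list = field(default_factory=list)
    drop_log: pd.DataFrame = None

    def __post_init__(self) -> None:
        self.beta_exp = np.asarray(self.beta_exp, dtype=float)
        self.se_exp = np.asarray(self.se_exp, dtype=float)
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        L, K = len(self.snp_ids), len(self.exposures)
        if self.beta_exp.shape != (L, K) or self.se_exp.shape != (L, K):
            raise ValueError("exposure matrices must be L x K")
        if np.isnan(self.beta_exp).any() or np.isnan(self.beta_out).any():
            raise ValueError("MVMR design contains missing cells after assembly")
        if L <= K:
            raise EstimationError(
                f"MVMR needs more instruments ({L}) than exposures ({K})"
            )
        if self.drop_log is None:
            self.drop_log = pd.DataFrame(columns=["snp_id", "reason"])

    @property
    def L(self) -> int:
        return len(self.snp_ids)

    @property
    def K(self) -> int:
        return len(self.exposures)


@dataclass
class MVMREstimate:
    """Per-exposure direct effects; intercept populated by the Egger variant."""

    estimates: dict            # exposure name -> MREstimate
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_pval: Optional[float] = None


def assemble_mvmr(
    exposures: Sequence[SumStatTable],
    outcome: SumStatTable,
    ld: LDReference,
    cfg: SelectionConfig,
) -> MVMRSet:
    """Build the joint instrument set for several exposures and one outcome.

    Steps: per-exposure significance screen; union of the selected SNPs
    ranked by the minimum p across exposures; joint greedy LD clump; then
    every exposure's effect (significant there or not) and the outcome
    effect extracted and allele-aligned to the contributing exposure's
    effect allele.  SNPs absent from any table are dropped with a logged
    reason.  An exposure left with no contributed instrument after
    clumping is excluded from the design and reported (a warning names
    it).
    """
    if len(exposures) < 2:
        raise ValueError("multivariable MR needs at least two exposures")

    # union of genome-wide-significant SNPs, keyed by minimum p
    best: dict[str, tuple] = {}  # snp_id -> (pval, exposure_index)
    for k, table in enumerate(exposures):
        selected = select_instruments(table, cfg)
        for row in selected.data.itertuples():
            if row.snp_id not in best or row.pval < best[row.snp_id][0]:
                best[row.snp_id] = (row.pval, k)

    if not best:
        raise HarmonizationError("no exposure contributes a significant instrument")

    union_rows = []
    for snp_id, (pval, k) in best.items():
        src = exposures[k].get(snp_id)
        union_rows.append(
            {
                "snp_id": snp_id,
                "chrom": src.chrom,
                "pos": src.pos,
                "effect_allele": src.effect_allele,
                "other_allele": src.other_allele,
                "eaf": src.eaf,
                "beta": src.beta,
                "se": src.se,
                "pval": pval,
                "source": k,
            }
        )
    union = pd.DataFrame(union_rows)
    union_table = SumStatTable("joint", "continuous",
                               union.drop(columns=["source"]))
    clumped = ld_clump(union_table, ld, cfg)
    kept_ids = list(clumped.data["snp_id"])
    source = {r["snp_id"]: r["source"] for r in union_rows}

    contributed = {k: 0 for k in range(len(exposures))}
    drop_rows = []
    rows = []
    for snp_id in kept_ids:
        k_src = source[snp_id]
        ref = exposures[k_src].get(snp_id)
        betas = np.full(len(exposures), np.nan)
        ses = np.full(len(exposures), np.nan)
        ok = True
        for k, table in enumerate(exposures):
            if snp_id not in table:
                drop_rows.append((snp_id, f"absent-from-{table.trait_name}"))
                ok = False
                break
            rec = table.get(snp_id)
            aligned = _align_alleles(ref, rec, cfg)
            if aligned is None or isinstance(aligned, str):
                drop_rows.append((snp_id, f"{aligned or 'incompatible-alleles'}"
                                          f"-in-{table.trait_name}"))
                ok = False
                break
            betas[k] = aligned[0]
            ses[k] = rec.se
        if not ok:
            continue
        if snp_id not in outcome:
            drop_rows.append((snp_id, f"absent-from-{outcome.trait_name}"))
            continue
        out_rec = outcome.get(snp_id)
        aligned = _align_alleles(ref, out_rec, cfg)
        if aligned is None or isinstance(aligned, str):
            drop_rows.append((snp_id, f"{aligned or 'incompatible-alleles'}"
                                      f"-in-{outcome.trait_name}"))
            continue
        rows.append((snp_id, betas, ses, aligned[0], out_rec.se))
        contributed[k_src] += 1

    instrumentless = [
        exposures[k].trait_name for k, c in contributed.items() if c == 0
    ]
    for name in instrumentless:
        warnings.warn(
            f"exposure {name!r} contributes no instrument after joint clumping; "
            "it is excluded from the multivariable model",
            stacklevel=2,
        )
    keep_k = [k for k in range(len(exposures))
              if exposures[k].trait_name not in instrumentless]
    if not rows:
        raise HarmonizationError("no SNPs survive multivariable assembly")

    ids = [r[0] for r in rows]
    beta_exp = np.vstack([r[1] for r in rows])[:, keep_k]
    se_exp = np.vstack([r[2] for r in rows])[:, keep_k]
    beta_out = np.array([r[3] for r in rows])
    se_out = np.array([r[4] for r in rows])

    return MVMRSet(
        exposures=[exposures[k].trait_name for k in keep_k],
        snp_ids=ids,
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        outcome_name=outcome.trait_name,
        outcome_binary=(outcome.trait_type == "binary"),
        instrumentless=instrumentless,
        drop_log=pd.DataFrame(drop_rows, columns=["snp_id", "reason"]),
    )


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        k = X.shape[1]
        worst = (0, 1, 0.0)
        for i in range(k):
            for j in range(i + 1, k):
                if abs(corr[i, j]) > abs(worst[2]):
                    worst = (i, j, corr[i, j])
        raise EstimationError(
            f"rank-deficient MVMR design: columns {names[worst[0]]!r} and "
            f"{names[worst[1]]!r} are collinear (correlation {worst[2]:.4f})"
        )


def _wls_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray, dof: int):
    """WLS solve with multiplicative overdispersion floored at 1.

    Returns (coef, se, q_resid, dispersion).
    """
    Xw = X * w[:, None]
    xtwx = X.T @ Xw
    coef = np.linalg.solve(xtwx, Xw.T @ y)
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    dispersion = np.sqrt(max(1.0, q / dof)) if dof > 0 else 1.0
    cov = np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov)) * dispersion
    return coef, se, q, dispersion


def mvmr_ivw(s: MVMRSet) -> MVMREstimate:
    """Multivariable IVW: WLS of beta_out on the exposure columns, no intercept.

    Weights 1/se_out^2; coefficient k is the direct effect of exposure k
    conditioning on the rest; SEs carry multiplicative overdispersion
    sqrt(max(1, Q_resid/(L-K))).
    """
    _check_rank(s.beta_exp, s.exposures)
    w = 1.0 / s.se_out**2
    coef, se, _, _ = _wls_fit(s.beta_exp, s.beta_out, w, s.L - s.K)
    estimates = {
        name: _estimate("mvmr_ivw", s.L, coef[k], se[k], s.outcome_binary)
        for k, name in enumerate(s.exposures)
    }
    return MVMREstimate(estimates=estimates)


def mvmr_egger(s: MVMRSet, primary: int = 0) -> MVMREstimate:
    """Multivariable MR-Egger: adds an intercept after orienting every SNP
    so its effect on the designated primary exposure is non-negative."""
    if s.L <= s.K + 1:
        raise EstimationError(
            f"multivariable Egger needs more instruments ({s.L}) than "
            f"exposures plus intercept ({s.K + 1})"
        )
    sign = np.where(s.beta_exp[:, primary] < 0, -1.0, 1.0)
    X = np.column_stack([np.ones(s.L), s.beta_exp * sign[:, None]])
    y = s.beta_out * sign
    _check_rank(X[:, 1:], s.exposures)
    w = 1.0 / s.se_out**2
    coef, se, _, _ = _wls_fit(X, y, w, s.L - s.K - 1)
    estimates = {
        name: _estimate("mvmr_egger", s.L, coef[k + 1], se[k + 1], s.outcome_binary)
        for k, name in enumerate(s.exposures)
    }
    p_int = float(2.0 * stats.norm.sf(abs(coef[0] / se[0])))
    return MVMREstimate(
        estimates=estimates,
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_pval=p_int,
    )
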