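"""Instrument selection, LD clumping, harmonization, and instrument QC.

The pipeline implemented here mirrors standard two-sample MR practice:
genome-wide significance screening (p < 5e-8), greedy LD clumping
(r2 < 0.001 within a 10,000 kb window, lowest p retained), proxy
substitution for instruments missing from the outcome (r2 > 0.8),
allele harmonization with removal of palindromic SNPs at intermediate
allele frequency (MAF > 0.3), per-SNP F statistics (F > 10 retained),
and Steiger filtering against reverse causation.

All published thresholds are applied as strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import (
    COMPLEMENT,
    LDReference,
    SumStatRecord,
    SumStatTable,
)


class HarmonizationError(ValueError):
    """No instruments survive harmonization or filtering."""


@dataclass
class SelectionConfig:
    """Thresholds governing instrument selection and QC.

    Defaults are the conventional genome-wide pipeline settings: strict
    p < 5e-8 significance, clump at r2 < 0.001 within 10,000 kb, proxies
    require r2 > 0.8, palindromic SNPs dropped when MAF > 0.3, and
    per-SNP F > 10.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    proxy_min_r2: float = 0.8
    palindrome_maf_cutoff: float = 0.3
    f_min: float = 10.0
    alpha: float = 0.05
    # what to do with SNPs absent from the LD reference during clumping
    missing_ld_policy: str = "keep"  # "keep" (treat as independent) | "drop"

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        for name in ("clump_r2", "proxy_min_r2", "palindrome_maf_cutoff"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")
        if self.missing_ld_policy not in ("keep", "drop"):
            raise ValueError("missing_ld_policy must be 'keep' or 'drop'")


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure/outcome effect vectors for the instruments.

    All vectors are aligned on ``snp_ids``.  ``provenance`` records, per
    input SNP, whether it was kept as-is, sign-flipped, proxy-substituted,
    or dropped (with a machine-readable reason).
    """

    snp_ids: list
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf_exp: np.ndarray = None  # NaN where unknown
    eaf_out: np.ndarray = None
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    outcome_binary: bool = True
    provenance: pd.DataFrame = None

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        L = len(self.snp_ids)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (L,):
                raise ValueError(f"{name} must have length {L}")
            setattr(self, name, arr)
        for name in ("eaf_exp", "eaf_out"):
            arr = getattr(self, name)
            arr = np.full(L, np.nan) if arr is None else np.asarray(arr, dtype=float)
            setattr(self, name, arr)
        if L < 1:
            raise HarmonizationError("harmonized set must contain at least one SNP")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValueError("standard errors must be strictly positive")
        if self.provenance is None:
            self.provenance = pd.DataFrame(
                {"snp_id": self.snp_ids, "status": "kept", "detail": ""}
            )

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask) -> "HarmonizedSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in idx],
            beta_exp=self.beta_exp[idx],
            se_exp=self.se_exp[idx],
            beta_out=self.beta_out[idx],
            se_out=self.se_out[idx],
            eaf_exp=self.eaf_exp[idx],
            eaf_out=self.eaf_out[idx],
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            outcome_binary=self.outcome_binary,
            provenance=self.provenance,
        )


@dataclass
class InstrumentStats:
    """Per-SNP variance explained and F statistics, plus Steiger outputs."""

    snp_ids: list
    r2_exp: np.ndarray
    r2_out: np.ndarray
    f_stat: np.ndarray
    steiger_keep: np.ndarray
    steiger_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "r2_exp": self.r2_exp,
                "r2_out": self.r2_out,
                "f_stat": self.f_stat,
                "steiger_keep": self.steiger_keep,
            }
        )


# ---------------------------------------------------------------------------
# selection and clumping
# ---------------------------------------------------------------------------

def select_instruments(table: SumStatTable, cfg: SelectionConfig) -> SumStatTable:
    """Keep variants with p strictly below the significance threshold."""
    mask = table.data["pval"] < cfg.p_threshold
    out = SumStatTable(table.trait_name, table.trait_type,
                       table.data[mask].reset_index(drop=True),
                       diagnostics=list(table.diagnostics))
    if len(out) == 0:
        out.diagnostics.append(
            f"no variants pass p < {cfg.p_threshold:g} for {table.trait_name}"
        )
    return out


def ld_clump(
    table: SumStatTable,
    ld: LDReference,
    cfg: SelectionConfig,
) -> SumStatTable:
    """Greedy p-value-ranked clumping.

    Repeatedly takes the lowest-p remaining variant as the index and drops
    every remaining variant on the same chromosome within
    ``clump_window_kb`` whose r2 with the index is >= ``clump_r2``.
    Variants absent from the LD reference follow ``missing_ld_policy``.
    Output is ordered by p-value.
    """
    df = table.data
    diagnostics = list(table.diagnostics)
    known = df["snp_id"].apply(
        lambda s: s in ld.positions or bool(ld.partners(s))
    )
    if cfg.missing_ld_policy == "drop" and (~known).any():
        dropped = df.loc[~known, "snp_id"].tolist()
        diagnostics.append(
            "dropped (absent from LD reference): " + ", ".join(dropped)
        )
        df = df[known]
    elif (~known).any():
        diagnostics.append(
            "kept as independent (absent from LD reference): "
            + ", ".join(df.loc[~known, "snp_id"].tolist())
        )

    order = df.sort_values(["pval", "snp_id"], kind="mergesort").reset_index(drop=True)
    remaining = list(order.index)
    pos = {
        row.snp_id: (row.chrom, row.pos)
        for row in order.itertuples()
        if not pd.isna(row.pos)
    }
    kept_ids = []
    while remaining:
        i = remaining.pop(0)
        index_snp = order.loc[i, "snp_id"]
        kept_ids.append(index_snp)
        idx_chrom, idx_pos = pos.get(index_snp, (None, None))
        survivors = []
        for j in remaining:
            snp = order.loc[j, "snp_id"]
            chrom, bp = pos.get(snp, (None, None))
            same_chrom = (
                idx_chrom is not None and chrom is not None and chrom == idx_chrom
            )
            in_window = (
                same_chrom
                and bp is not None
                and idx_pos is not None
                and abs(int(bp) - int(idx_pos)) <= cfg.clump_window_kb * 1000
            )
            if in_window and ld.r2(index_snp, snp) >= cfg.clump_r2:
                diagnostics.append(
                    f"clumped out {snp} (r2 >= {cfg.clump_r2:g} with index {index_snp})"
                )
                continue
            survivors.append(j)
        remaining = survivors

    out_df = order[order["snp_id"].isin(kept_ids)].reset_index(drop=True)
    return SumStatTable(table.trait_name, table.trait_type, out_df,
                        diagnostics=diagnostics)


def find_proxy(
    target: str,
    outcome: SumStatTable,
    ld: LDReference,
    cfg: SelectionConfig,
) -> Optional[str]:
    """Best outcome-present proxy for ``target`` with r2 strictly above threshold.

    Ties on r2 break by smaller base-pair distance, then lexicographic id.
    Returns ``None`` when no qualifying proxy exists.
    """
    present = set(outcome.data["snp_id"])
    target_pos = ld.positions.get(target)
    candidates = []
    for snp, r2 in ld.partners(target).items():
        if snp not in present or not (r2 > cfg.proxy_min_r2):
            continue
        cand_pos = ld.positions.get(snp)
        if target_pos is not None and cand_pos is not None:
            dist = abs(cand_pos[1] - target_pos[1])
        else:
            dist = np.inf
        candidates.append((-r2, dist, snp))
    if not candidates:
        return None
    candidates.sort()
    return candidates[0][2]


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


def _maf(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


def harmonize(
    exposure: SumStatTable,
    outcome: SumStatTable,
    cfg: SelectionConfig,
    ld: Optional[LDReference] = None,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    Rules, per exposure SNP found in the outcome (directly, or via the
    best LD proxy when ``ld`` is supplied):

    * alleles identical -> keep as-is;
    * alleles swapped (effect <-> other) -> negate outcome beta and
      complement its EAF;
    * alleles match on the opposite strand -> same two rules after
      complementing;
    * palindromic (A/T, C/G) with MAF > ``palindrome_maf_cutoff`` in
      either table, or with EAF unavailable -> dropped (strand cannot be
      adjudicated);
    * palindromic with low MAF -> aligned by EAF concordance (effect
      allele frequencies must fall on the same side of 0.5; a discordant
      pair implies a strand flip and the outcome beta is negated);
    * irreconcilable allele sets -> dropped.
    """
    out_by_id = {r["snp_id"]: i for i, r in outcome.data.iterrows()}
    prov_rows = []
    rows = []

    for exp_rec in exposure.records():
        status, detail = "kept", ""
        out_rec = None
        if exp_rec.snp_id in out_by_id:
            out_rec = outcome.get(exp_rec.snp_id)
        elif ld is not None:
            proxy = find_proxy(exp_rec.snp_id, outcome, ld, cfg)
            if proxy is not None:
                out_rec = outcome.get(proxy)
                status = "proxy"
                detail = f"proxy={proxy} (LD correlation sign assumed positive)"
        if out_rec is None:
            prov_rows.append((exp_rec.snp_id, "dropped", "absent-from-outcome"))
            continue

        if status == "proxy":
            aligned = _align_proxy(exp_rec, out_rec)
            if aligned is None:
                prov_rows.append((exp_rec.snp_id, "dropped",
                                  "proxy-eaf-unavailable"))
                continue
            beta_out, eaf_out, flipped = aligned
            if flipped:
                detail += "; proxy EAF-aligned by flip"
        else:
            result = _align_alleles(exp_rec, out_rec, cfg)
            if result is None or isinstance(result, str):
                prov_rows.append((exp_rec.snp_id, "dropped",
                                  result or "incompatible-alleles"))
                continue
            beta_out, eaf_out, flipped = result
            if flipped:
                status = "flipped" if status == "kept" else status
                detail = (detail + "; " if detail else "") + "outcome beta negated"

        prov_rows.append((exp_rec.snp_id, status, detail))
        rows.append(
            (
                exp_rec.snp_id,
                exp_rec.beta,
                exp_rec.se,
                beta_out,
                out_rec.se,
                np.nan if exp_rec.eaf is None else exp_rec.eaf,
                np.nan if eaf_out is None else eaf_out,
            )
        )

    provenance = pd.DataFrame(prov_rows, columns=["snp_id", "status", "detail"])
    if not rows:
        raise HarmonizationError(
            f"no SNPs could be harmonized between {exposure.trait_name} "
            f"and {outcome.trait_name}"
        )
    ids, bx, sx, by, sy, fx, fy = zip(*rows)
    return HarmonizedSet(
        snp_ids=list(ids),
        beta_exp=np.array(bx),
        se_exp=np.array(sx),
        beta_out=np.array(by),
        se_out=np.array(sy),
        eaf_exp=np.array(fx),
        eaf_out=np.array(fy),
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        outcome_binary=(outcome.trait_type == "binary"),
        provenance=provenance,
    )


def _align_alleles(exp_rec: SumStatRecord, out_rec: SumStatRecord,
                   cfg: SelectionConfig):
    """Return (beta_out, eaf_out, flipped) or a drop-reason string or None."""
    ea, oa = exp_rec.effect_allele, exp_rec.other_allele
    ea2, oa2 = out_rec.effect_allele, out_rec.other_allele
    beta_out, eaf_out = out_rec.beta, out_rec.eaf
    palindromic = _is_palindromic(ea, oa)

    if palindromic:
        if {ea2, oa2} != {ea, oa}:
            return "incompatible-alleles"
        if exp_rec.eaf is None or out_rec.eaf is None:
            return "palindromic-missing-eaf"
        if (_maf(exp_rec.eaf) > cfg.palindrome_maf_cutoff
                or _maf(out_rec.eaf) > cfg.palindrome_maf_cutoff):
            return "palindromic-intermediate-maf"
        flipped = False
        if ea2 == oa and oa2 == ea:  # label-swapped relative to exposure
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
            flipped = True
        # strand adjudication: EAFs must sit on the same side of 0.5
        same_side = (exp_rec.eaf - 0.5) * (eaf_out - 0.5) > 0
        if not same_side:
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
            flipped = not flipped
        return beta_out, eaf_out, flipped

    comp_ea2 = COMPLEMENT.get(ea2)
    comp_oa2 = COMPLEMENT.get(oa2)
    if (ea2, oa2) == (ea, oa):
        return beta_out, eaf_out, False
    if (ea2, oa2) == (oa, ea):
        return -beta_out, None if eaf_out is None else 1.0 - eaf_out, True
    if (comp_ea2, comp_oa2) == (ea, oa):
        return beta_out, eaf_out, False
    if (comp_ea2, comp_oa2) == (oa, ea):
        return -beta_out, None if eaf_out is None else 1.0 - eaf_out, True
    return "incompatible-alleles"


def _align_proxy(exp_rec: SumStatRecord, proxy_rec: SumStatRecord):
    """Orient a proxy's outcome effect to the exposure SNP's effect allele.

    A pair list stores r2 without sign, so the LD correlation is assumed
    positive; when both EAFs are available the proxy allele whose
    frequency falls on the exposure effect allele's side of 0.5 is taken
    as concordant.  Returns (beta_out, eaf_out, flipped) or None when the
    exposure SNP's EAF is unavailable (orientation impossible).
    """
    if exp_rec.eaf is None or proxy_rec.eaf is None:
        return None
    same_side = (exp_rec.eaf - 0.5) * (proxy_rec.eaf - 0.5) > 0
    if same_side:
        return proxy_rec.beta, proxy_rec.eaf, False
    return -proxy_rec.beta, 1.0 - proxy_rec.eaf, True


# ---------------------------------------------------------------------------
# instrument strength
# ---------------------------------------------------------------------------

def compute_snp_r2(record: SumStatRecord, trait_type: Optional[str] = None):
    """Variance in the trait explained by one SNP.

    Continuous trait with EAF present: r2 = 2*eaf*(1-eaf)*beta^2 (the
    standardized-trait approximation).  Otherwise the z-based fallback
    r2 = z^2 / (z^2 + n) with z = beta/se, which requires n.

    Returns (r2, method) where method is "eaf" or "z".
    """
    trait_type = trait_type or ("binary" if record.n_case is not None else "continuous")
    if trait_type == "continuous" and record.eaf is not None:
        r2 = 2.0 * record.eaf * (1.0 - record.eaf) * record.beta**2
        return min(r2, 1.0 - np.finfo(float).eps), "eaf"
    if record.n is None:
        raise ValueError(
            f"{record.snp_id}: cannot compute r2 (needs EAF for a continuous "
            "trait or a sample size for the z-based fallback)"
        )
    z = record.beta / record.se
    return z**2 / (z**2 + record.n), "z"


def _vector_r2(beta, se, eaf, n, trait_type: str) -> np.ndarray:
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    eaf = np.asarray(eaf, float)
    z2 = (beta / se) ** 2
    z_fallback = z2 / (z2 + n)
    if trait_type == "continuous":
        freq = 2.0 * eaf * (1.0 - eaf) * beta**2
        return np.where(np.isnan(eaf), z_fallback, freq)
    return z_fallback


def f_statistic(record: SumStatRecord) -> float:
    """Single-instrument F approximation, F = (beta/se)^2."""
    return (record.beta / record.se) ** 2


def f_filter(h: HarmonizedSet, cfg: SelectionConfig):
    """Drop instruments whose per-SNP F is not strictly above ``f_min``.

    Returns (filtered set, F array over the input set).
    """
    f = (h.beta_exp / h.se_exp) ** 2
    keep = f > cfg.f_min
    if not keep.any():
        raise HarmonizationError("no instruments exceed the F threshold")
    return h.subset(keep), f


def steiger_filter(
    h: HarmonizedSet,
    n_exp: int,
    n_out: int,
    exposure_type: str = "binary",
    outcome_type: str = "binary",
):
    """Remove SNPs that explain more variance in the outcome than the exposure.

    Per SNP, r2 in each trait is computed via the same semantics as
    :func:`compute_snp_r2` (frequency formula for continuous traits with
    EAF, z-based fallback otherwise); SNPs with r2_out strictly greater
    than r2_exp are dropped.  A set-level directionality p-value is
    reported from the Fisher-z comparison of the aggregated correlations,

        z = (atanh r_exp - atanh r_out) / sqrt(1/(n_exp-3) + 1/(n_out-3)),

    with r = sqrt(sum of per-SNP r2) over the instruments.

    Returns (filtered HarmonizedSet, InstrumentStats).
    """
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("sample sizes must exceed 3 for the Fisher-z comparison")
    r2_exp = _vector_r2(h.beta_exp, h.se_exp, h.eaf_exp, n_exp, exposure_type)
    r2_out = _vector_r2(h.beta_out, h.se_out, h.eaf_out, n_out, outcome_type)
    keep = ~(r2_out > r2_exp)  # strict: ties kept (conservative)
    f = (h.beta_exp / h.se_exp) ** 2

    r_exp = np.sqrt(min(float(np.sum(r2_exp)), 1.0 - 1e-12))
    r_out = np.sqrt(min(float(np.sum(r2_out)), 1.0 - 1e-12))
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    steiger_p = float(2.0 * stats.norm.sf(abs(z)))

    stats_out = InstrumentStats(
        snp_ids=list(h.snp_ids),
        r2_exp=r2_exp,
        r2_out=r2_out,
        f_stat=f,
        steiger_keep=keep,
        steiger_p=steiger_p,
    )
    if not keep.any():
        raise HarmonizationError("no instruments survive Steiger filtering")
    return h.subset(keep), stats_out


def power_binary(
    n: int,
    case_prop: float,
    r2_sum: float,
    or_alt: float,
    alpha: float = 0.05,
) -> float:
    """Approximate power of the IVW test for a binary outcome.

    Normal approximation with non-centrality
    nu = |ln OR| * sqrt(n * r2_sum * k * (1 - k)); power is the two-sided
    rejection probability at level ``alpha``.
    """
    if not (0 < case_prop < 1):
        raise ValueError("case_prop must be in (0, 1)")
    if not (0 < r2_sum < 1):
        raise ValueError("r2_sum must be in (0, 1)")
    if or_alt <= 0:
        raise ValueError("or_alt must be positive")
    nu = abs(np.log(or_alt)) * np.sqrt(n * r2_sum * case_prop * (1 - case_prop))
    z_crit = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(nu - z_crit) + stats.norm.cdf(-nu - z_crit))
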