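"""Synthetic GWAS summary statistics with known causal ground truth.

The generator works entirely on the summary scale (no individual-level
genotypes): per-SNP true effects are drawn for an exposure, an arbitrary
number of mediators, and an outcome linked by a linear causal diagram

    exposure --a_k--> mediator_k --b_k--> outcome
    exposure --------------c'----------> outcome

so the total exposure effect is theta = c' + sum_k a_k * b_k.  Observed
estimates are the true per-SNP effects plus sampling noise with the
standard GWAS standard-error scaling: se = 1/sqrt(2 * MAF * (1-MAF) * n)
for continuous traits and se = 1/sqrt(2 * MAF * (1-MAF) * n * k * (1-k))
on the log-OR scale for binary traits with case fraction k.  Exposure,
mediator, and outcome samples are independent by construction (no sample
overlap).

Knobs cover the failure modes two-sample MR must be robust to:
directional or balanced pleiotropy (mu_alpha, sigma_alpha), correlation
between instrument strength and pleiotropy (inside_rho, violating the
InSIDE assumption), reverse-causal variants (primary outcome effects
inducing exposure effects), and block-structured LD.

The exposure-instrument panel emulates a list of loci already
ascertained at genome-wide significance, as a published instrument set
is: true effects are drawn as sign * (gamma_min + |N(0, sigma_gamma^2)|),
so nearly all instruments survive the p < 5e-8 screen at the default
sample sizes.  Setting ``gamma_min = 0`` recovers a plain centred
normal effect distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDReference, SumStatTable

# allele pairs used for synthetic variants; non-palindromic by default so
# harmonization is exact, with an optional palindromic fraction
_NON_PALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC = [("A", "T"), ("C", "G")]


@dataclass
class SimulationTruth:
    """The causal diagram: theta = c_prime + sum_k a_k * b_k (enforced)."""

    theta: float
    a: tuple = ()
    b: tuple = ()
    c_prime: float = None
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    inside_rho: float = 0.0
    n_reverse: int = 0

    def __post_init__(self) -> None:
        self.a = tuple(self.a)
        self.b = tuple(self.b)
        if len(self.a) != len(self.b):
            raise ValueError("a and b must have one entry per mediator")
        indirect = float(np.dot(self.a, self.b)) if self.a else 0.0
        if self.c_prime is None:
            self.c_prime = self.theta - indirect
        if abs(self.theta - (self.c_prime + indirect)) > 1e-12:
            raise ValueError(
                "inconsistent truth: theta must equal c_prime + sum(a_k * b_k)"
            )
        if not (-1.0 <= self.inside_rho <= 1.0):
            raise ValueError("inside_rho must be in [-1, 1]")
        if self.n_reverse < 0:
            raise ValueError("n_reverse must be non-negative")

    @property
    def n_mediators(self) -> int:
        return len(self.a)


@dataclass
class SimulationConfig:
    """Panel sizes, allele frequencies, effect scales, and GWAS sample sizes.

    Defaults mirror a large psychiatric two-sample design: 146 exposure
    instruments; a binary exposure GWAS of 130,644 (case fraction 0.409);
    a binary outcome GWAS of 143,265 (case fraction 0.318); continuous
    mediator GWASs of 462,464.
    """

    n_snps: int = 146                  # exposure instruments
    n_med_snps: int = 30               # mediator-specific instruments, per mediator
    n_null_snps: int = 0               # variants with no effect anywhere
    maf_range: tuple = (0.05, 0.5)
    sigma_gamma: float = 0.03          # spread of instrument effect magnitudes
    gamma_min: float = 0.08            # ascertainment floor on |effect|
    sigma_delta: float = 0.03          # spread for mediator-specific effects
    delta_min: float = 0.08
    reverse_scale: float = 2.0         # outcome-effect scale for reverse SNPs
    reverse_induction: float = 0.5     # induced exposure effect per unit outcome effect
    n_exp: int = 130_644
    n_out: int = 143_265
    n_med: int = 462_464
    case_prop_exp: float = 0.409
    case_prop_out: float = 0.318
    exposure_binary: bool = True
    outcome_binary: bool = True
    palindrome_fraction: float = 0.0
    ld_block_size: int = 1
    ld_block_r2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("n_snps", "n_exp", "n_out", "n_med", "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("case_prop_exp", "case_prop_out"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class SimulatedStudy:
    """Generated tables, LD reference, ground truth, and per-SNP roles."""

    exposure: SumStatTable
    mediators: list
    outcome: SumStatTable
    ld: LDReference
    truth: SimulationTruth
    roles: pd.DataFrame  # snp_id, role in {iv, mediator_k, reverse, null}
    true_effects: pd.DataFrame = None  # per-SNP noise-free effects per trait


def _se_continuous(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _se_binary(maf: np.ndarray, n: int, k: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * k * (1.0 - k))


def _observe(true_beta, se, rng) -> tuple[np.ndarray, np.ndarray]:
    beta_hat = true_beta + se * rng.standard_normal(len(se))
    pval = 2.0 * stats.norm.sf(np.abs(beta_hat / se))
    return beta_hat, np.clip(pval, np.finfo(float).tiny, 1.0)


def _table(name, trait_type, snp_ids, chrom, pos, ea, oa, eaf, beta, se, pval,
           n, n_case=None, n_control=None) -> SumStatTable:
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
            "n_case": n_case if n_case is not None else pd.NA,
            "n_control": n_control if n_control is not None else pd.NA,
        }
    )
    return SumStatTable(name, trait_type, df)


def simulate_study(
    cfg: SimulationConfig,
    truth: SimulationTruth,
    seed: Optional[int] = None,
) -> SimulatedStudy:
    """Draw one synthetic study (exposure, mediators, outcome, LD reference).

    The same (cfg, truth, seed) triple always produces byte-identical
    tables.  ``seed`` overrides ``cfg.seed`` when given.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    K = truth.n_mediators

    roles = (
        ["iv"] * cfg.n_snps
        + [f"mediator_{k}" for k in range(K) for _ in range(cfg.n_med_snps)]
        + ["reverse"] * truth.n_reverse
        + ["null"] * cfg.n_null_snps
    )
    total = len(roles)
    snp_ids = [f"rs{i + 1:07d}" for i in range(total)]
    roles_df = pd.DataFrame({"snp_id": snp_ids, "role": roles})

    maf = rng.uniform(*cfg.maf_range, size=total)
    eaf = np.where(rng.random(total) < 0.5, maf, 1.0 - maf)

    pair_pool = _NON_PALINDROMIC + _PALINDROMIC
    is_pal = rng.random(total) < cfg.palindrome_fraction
    pair_idx = np.where(
        is_pal,
        rng.integers(len(_NON_PALINDROMIC), len(pair_pool), size=total),
        rng.integers(0, len(_NON_PALINDROMIC), size=total),
    )
    ea = np.array([pair_pool[i][0] for i in pair_idx])
    oa = np.array([pair_pool[i][1] for i in pair_idx])

    # LD blocks: consecutive SNPs grouped, 1 kb spacing inside a block,
    # blocks 20 Mb apart, all on one synthetic chromosome
    block = np.arange(total) // cfg.ld_block_size
    within = np.arange(total) % cfg.ld_block_size
    pos = block * 20_000_000 + within * 1000 + 1
    chrom = np.full(total, "1")
    positions = {s: ("1", int(p)) for s, p in zip(snp_ids, pos)}
    ld = LDReference(positions=positions)
    if cfg.ld_block_size > 1 and cfg.ld_block_r2 > 0:
        for b in range(block.max() + 1):
            members = np.flatnonzero(block == b)
            for i_idx in range(len(members)):
                for j_idx in range(i_idx + 1, len(members)):
                    ld.add_pair(snp_ids[members[i_idx]],
                                snp_ids[members[j_idx]], cfg.ld_block_r2)

    role_arr = np.array(roles)
    iv_mask = role_arr == "iv"
    rev_mask = role_arr == "reverse"

    # true exposure effects
    g = np.zeros(total)
    magnitudes = cfg.gamma_min + np.abs(rng.normal(0, cfg.sigma_gamma, cfg.n_snps))
    g[iv_mask] = rng.choice([-1.0, 1.0], cfg.n_snps) * magnitudes

    # reverse-causal variants: primary outcome effects inducing exposure effects
    o_rev = np.zeros(total)
    if truth.n_reverse:
        rev_mag = cfg.reverse_scale * (
            cfg.gamma_min + np.abs(rng.normal(0, cfg.sigma_gamma, truth.n_reverse))
        )
        o_rev[rev_mask] = rng.choice([-1.0, 1.0], truth.n_reverse) * rev_mag
        g[rev_mask] = cfg.reverse_induction * o_rev[rev_mask]

    # mediator truth: a_k * exposure effect plus mediator-specific instruments
    m_true = np.zeros((total, K))
    for k in range(K):
        m_true[:, k] = truth.a[k] * g
        med_mask = role_arr == f"mediator_{k}"
        mags = cfg.delta_min + np.abs(rng.normal(0, cfg.sigma_delta, cfg.n_med_snps))
        m_true[med_mask, k] += rng.choice([-1.0, 1.0], cfg.n_med_snps) * mags

    # pleiotropy: drawn in the frame where each instrument is oriented to
    # its exposure-raising allele (the frame in which "directional" is
    # meaningful), then mapped back; instrument strength = |effect|, so
    # inside_rho > 0 correlates pleiotropy with strength (InSIDE violation)
    alpha = np.zeros(total)
    if cfg.n_snps and (truth.sigma_alpha > 0 or truth.mu_alpha != 0):
        eps = rng.standard_normal(cfg.n_snps)
        mag = np.abs(g[iv_mask])
        mag_std = (mag - mag.mean()) / (mag.std() if mag.std() > 0 else 1.0)
        oriented = truth.mu_alpha + truth.sigma_alpha * (
            truth.inside_rho * mag_std
            + np.sqrt(1.0 - truth.inside_rho**2) * eps
        )
        alpha[iv_mask] = np.sign(g[iv_mask]) * oriented

    y_true = truth.c_prime * g + m_true @ np.array(truth.b or []) + alpha + o_rev

    # observed summaries with independent sampling noise per table
    if cfg.exposure_binary:
        se_exp = _se_binary(maf, cfg.n_exp, cfg.case_prop_exp)
        n_case_e = int(round(cfg.n_exp * cfg.case_prop_exp))
        exp_counts = dict(n_case=n_case_e, n_control=cfg.n_exp - n_case_e)
    else:
        se_exp = _se_continuous(maf, cfg.n_exp)
        exp_counts = {}
    bx, px = _observe(g, se_exp, rng)
    exposure = _table("exposure", "binary" if cfg.exposure_binary else "continuous",
                      snp_ids, chrom, pos, ea, oa, eaf, bx, se_exp, px,
                      cfg.n_exp, **exp_counts)

    mediators = []
    for k in range(K):
        se_m = _se_continuous(maf, cfg.n_med)
        bm, pm = _observe(m_true[:, k], se_m, rng)
        mediators.append(
            _table(f"mediator_{k}", "continuous", snp_ids, chrom, pos, ea, oa,
                   eaf, bm, se_m, pm, cfg.n_med)
        )

    if cfg.outcome_binary:
        se_out = _se_binary(maf, cfg.n_out, cfg.case_prop_out)
        n_case_o = int(round(cfg.n_out * cfg.case_prop_out))
        out_counts = dict(n_case=n_case_o, n_control=cfg.n_out - n_case_o)
    else:
        se_out = _se_continuous(maf, cfg.n_out)
        out_counts = {}
    by, py = _observe(y_true, se_out, rng)
    outcome = _table("outcome", "binary" if cfg.outcome_binary else "continuous",
                     snp_ids, chrom, pos, ea, oa, eaf, by, se_out, py,
                     cfg.n_out, **out_counts)

    true_effects = pd.DataFrame({"snp_id": snp_ids, "exposure": g,
                                 "outcome": y_true})
    for k in range(K):
        true_effects[f"mediator_{k}"] = m_true[:, k]

    return SimulatedStudy(
        exposure=exposure,
        mediators=mediators,
        outcome=outcome,
        ld=ld,
        truth=truth,
        roles=roles_df,
        true_effects=true_effects,
    )


def truth_report(truth: SimulationTruth) -> dict:
    """Machine-readable ground truth with the implied mediation proportions."""
    indirect = [a * b for a, b in zip(truth.a, truth.b)]
    report = {
        "theta": truth.theta,
        "a": list(truth.a),
        "b": list(truth.b),
        "c_prime": truth.c_prime,
        "mu_alpha": truth.mu_alpha,
        "sigma_alpha": truth.sigma_alpha,
        "inside_rho": truth.inside_rho,
        "n_reverse": truth.n_reverse,
        "indirect": indirect,
        "proportion_pct": [
            100.0 * ab / truth.theta if truth.theta != 0 else float("nan")
            for ab in indirect
        ],
        "total_proportion_pct": (
            100.0 * sum(indirect) / truth.theta if truth.theta != 0 else float("nan")
        ),
    }
    return report


def write_truth(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_report(truth), fh, indent=2)
        fh.write("\n")
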