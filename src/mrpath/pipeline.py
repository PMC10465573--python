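"""Config-driven orchestration of the full study design.

``run_bidirectional`` runs the complete instrument pipeline and estimator
suite in both directions between two traits, applying the SIMEX trigger
(I2_GX < 0.9), the MR-PRESSO adoption rule (outlier-corrected estimate
adopted only when both global and distortion tests are significant), and
Steiger filtering, and emits per-direction tables plus a sensitivity
table and a structured run log.  ``run_full_study`` adds the two-step
mediation analysis and its multivariable-MR table.

Every random procedure's seed is recorded in the run log; a fixed config
and seed produce a byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import report
from .instruments import (
    SelectionConfig,
    f_filter,
    harmonize,
    ld_clump,
    select_instruments,
    steiger_filter,
)
from .mediation import _table_n, two_step_mediation
from .mr_presso import presso, presso_report
from .mvmr import assemble_mvmr, mvmr_egger, mvmr_ivw
from .sumstats import (
    LDReference,
    SumStatTable,
    load_ld_reference,
    read_sumstats,
)
from .uni_mr import (
    EstimationError,
    cochran_q,
    egger,
    egger_simex,
    ivw,
    leave_one_out,
    single_snp,
    weighted_median,
)


@dataclass
class AnalysisConfig:
    """Inputs and settings for a full study run."""

    exposure: SumStatTable
    outcome: SumStatTable
    ld: LDReference
    mediators: list = field(default_factory=list)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0
    i2_cutoff: float = 0.9
    presso_nsim: int = 1000
    simex_boot: int = 1000
    wm_boot: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.i2_cutoff <= 1):
            raise ValueError("i2_cutoff must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        """Load a YAML document naming file paths and settings.

        Expected keys: ``exposure``/``outcome``/``mediators`` (each with
        ``path``, ``trait_type`` and optional ``name``/``column_map``),
        ``ld`` (pair-list path), optional ``selection`` overrides, and
        scalar settings (seed, i2_cutoff, presso_nsim, ...).
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh)

        def _load(spec):
            return read_sumstats(
                spec["path"],
                trait_type=spec["trait_type"],
                column_map=spec.get("column_map"),
                trait_name=spec.get("name"),
            )

        sel = SelectionConfig(**doc.get("selection", {}))
        return cls(
            exposure=_load(doc["exposure"]),
            outcome=_load(doc["outcome"]),
            ld=load_ld_reference(doc["ld"]),
            mediators=[_load(m) for m in doc.get("mediators", [])],
            selection=sel,
            seed=int(doc.get("seed", 0)),
            i2_cutoff=float(doc.get("i2_cutoff", 0.9)),
            presso_nsim=int(doc.get("presso_nsim", 1000)),
            simex_boot=int(doc.get("simex_boot", 1000)),
            wm_boot=int(doc.get("wm_boot", 1000)),
        )


def _run_direction(
    exposure: SumStatTable,
    outcome: SumStatTable,
    cfg: AnalysisConfig,
    log: list,
) -> dict:
    """Instrument pipeline + estimator suite for one direction."""
    sel = cfg.selection
    label = f"{exposure.trait_name}->{outcome.trait_name}"
    iv = ld_clump(select_instruments(exposure, sel), cfg.ld, sel)
    log.append({"stage": "select+clump", "direction": label,
                "n_instruments": len(iv)})
    if len(iv) == 0:
        log.append({"stage": "abort", "direction": label,
                    "reason": "no significant instruments"})
        return {"direction": label, "estimates": [], "sensitivity": {},
                "n_snps": 0}

    h = harmonize(iv, outcome, sel, ld=cfg.ld)
    h, f_stats = f_filter(h, sel)
    n_exp, n_out = _table_n(exposure), _table_n(outcome)
    steiger_p = None
    if n_exp is not None and n_out is not None:
        h, inst_stats = steiger_filter(
            h, n_exp, n_out,
            exposure_type=exposure.trait_type,
            outcome_type=outcome.trait_type,
        )
        steiger_p = inst_stats.steiger_p
    dropped = h.provenance[h.provenance["status"] == "dropped"]
    for row in dropped.itertuples():
        log.append({"stage": "harmonize", "direction": label,
                    "snp_id": row.snp_id, "dropped": row.detail})
    log.append({"stage": "qc", "direction": label, "n_snps": len(h),
                "min_f": float(np.min((h.beta_exp / h.se_exp) ** 2)),
                "steiger_p": steiger_p})

    estimates = []
    sensitivity: dict = {"direction": label, "steiger_p": steiger_p}
    L = len(h)
    main = ivw(h)
    if L < 3:
        log.append({"stage": "estimate", "direction": label,
                    "warning": f"only {L} instruments; degraded to Wald/IVW"})
        estimates.append(main)
        return {"direction": label, "estimates": estimates,
                "sensitivity": sensitivity, "n_snps": L, "harmonized": h}

    eg = egger(h)
    sensitivity.update(
        egger_intercept=eg.intercept,
        egger_intercept_p=eg.intercept_pval,
        i2_gx=eg.i2_gx,
        rucker_q=eg.rucker_q.statistic,
        rucker_q_p=eg.rucker_q.pval,
    )
    if eg.i2_gx < cfg.i2_cutoff:
        # measurement error in the SNP-exposure estimates attenuates the
        # Egger slope; replace it with the SIMEX-corrected fit
        est_egger = egger_simex(h, n_boot=cfg.simex_boot, seed=cfg.seed)
        log.append({"stage": "simex", "direction": label,
                    "i2_gx": eg.i2_gx, "seed": cfg.seed})
    else:
        est_egger = eg.slope
    estimates.append(est_egger)
    estimates.append(weighted_median(h, n_boot=cfg.wm_boot, seed=cfg.seed))
    estimates.append(main)

    q = cochran_q(h, main.beta)
    sensitivity.update(cochran_q=q.statistic, cochran_q_p=q.pval)

    if L >= 4:
        pres = presso(h, n_sim=cfg.presso_nsim, seed=cfg.seed,
                      alpha=sel.alpha)
        sensitivity.update(
            presso_global_p=pres.global_p,
            presso_outliers=",".join(pres.outliers),
            presso_distortion_p=pres.distortion_p,
        )
        log.append({"stage": "presso", "direction": label,
                    "seed": cfg.seed, **presso_report(main, pres)})
        adopted = (
            pres.global_p < sel.alpha
            and pres.distortion_p is not None
            and pres.distortion_p < sel.alpha
        )
        sensitivity["presso_adopted"] = adopted
        if pres.outliers:
            estimates.append(pres.corrected)

    loo = leave_one_out(h, alpha=sel.alpha)
    sensitivity["loo_flags"] = int(
        (loo["sign_change"] | loo["significance_change"]).sum()
    )
    return {
        "direction": label,
        "estimates": estimates,
        "sensitivity": sensitivity,
        "n_snps": L,
        "harmonized": h,
        "single_snp": single_snp(h),
        "leave_one_out": loo,
    }


def run_bidirectional(cfg: AnalysisConfig) -> dict:
    """Univariable MR in both directions, with the full sensitivity suite."""
    log: list = [{"stage": "config", "seed": cfg.seed,
                  "p_threshold": cfg.selection.p_threshold,
                  "clump_r2": cfg.selection.clump_r2,
                  "i2_cutoff": cfg.i2_cutoff}]
    forward = _run_direction(cfg.exposure, cfg.outcome, cfg, log)
    reverse = _run_direction(cfg.outcome, cfg.exposure, cfg, log)
    bundle = {
        "forward": forward,
        "reverse": reverse,
        "runlog": log,
        "table1_forward": report.estimates_table(
            forward["estimates"], cfg.outcome.trait_name,
            cfg.outcome.trait_type == "binary"),
        "table1_reverse": report.estimates_table(
            reverse["estimates"], cfg.exposure.trait_name,
            cfg.exposure.trait_type == "binary"),
        "sensitivity": pd.DataFrame(
            [forward["sensitivity"], reverse["sensitivity"]]),
    }
    return bundle


def run_full_study(cfg: AnalysisConfig) -> dict:
    """Bidirectional MR plus two-step mediation through the mediators."""
    bundle = run_bidirectional(cfg)
    log = bundle["runlog"]
    if not cfg.mediators:
        bundle["table3"] = pd.DataFrame()
        bundle["mediation_status"] = "no mediators configured"
        return bundle

    results, status = two_step_mediation(
        cfg.exposure, cfg.mediators, cfg.outcome, cfg.ld,
        cfg=cfg.selection, seed=cfg.seed,
    )
    bundle["mediation_results"] = results
    bundle["mediation_status"] = status
    bundle["table3"] = report.mediation_table(results)
    log.append({"stage": "mediation", "status": status,
                "mediators": [r.mediator for r in results]})

    gated = [m for m in cfg.mediators
             if any(r.mediator == m.trait_name for r in results)]
    if gated:
        mv_set = assemble_mvmr([cfg.exposure, *gated], cfg.outcome,
                               cfg.ld, cfg.selection)
        mv_ivw = mvmr_ivw(mv_set)
        try:
            mv_eg = mvmr_egger(mv_set)
        except EstimationError:
            mv_eg = None
        bundle["mvmr_set"] = mv_set
        bundle["table2"] = report.mvmr_table(mv_set, mv_ivw, mv_eg)
        log.append({"stage": "mvmr", "n_snps": mv_set.L,
                    "exposures": mv_set.exposures,
                    "instrumentless": mv_set.instrumentless})
    else:
        bundle["table2"] = pd.DataFrame()
    return bundle


def write_bundle(bundle: dict, outdir) -> Path:
    """Write the report bundle (TSV tables, machine JSON, JSONL run log)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in ("table1_forward", "table1_reverse", "sensitivity",
                "table2", "table3"):
        if key in bundle and isinstance(bundle[key], pd.DataFrame):
            bundle[key].to_csv(outdir / f"{key}.tsv", sep="\t", index=False)
    machine = {}
    for side in ("forward", "reverse"):
        if side in bundle:
            machine[side] = {
                "direction": bundle[side]["direction"],
                "n_snps": bundle[side]["n_snps"],
                "estimates": [report.estimate_to_dict(e)
                              for e in bundle[side]["estimates"]],
                "sensitivity": {
                    k: v for k, v in bundle[side]["sensitivity"].items()
                },
            }
    if "mediation_results" in bundle:
        machine["mediation"] = [
            {
                "mediator": r.mediator,
                "total": r.total.beta,
                "a": r.a, "se_a": r.se_a,
                "b": r.b, "se_b": r.se_b,
                "indirect": r.indirect,
                "se_indirect": r.se_indirect,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "proportion_pct": r.proportion_pct,
                "inconsistent": r.inconsistent,
            }
            for r in bundle["mediation_results"]
        ]
        machine["mediation_status"] = bundle["mediation_status"]
    report.write_json(machine, outdir / "full_precision.json")
    with open(outdir / "runlog.jsonl", "w") as fh:
        for rec in bundle["runlog"]:
            fh.write(json.dumps(rec, sort_keys=True, default=report._json_default))
            fh.write("\n")
    return outdir
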