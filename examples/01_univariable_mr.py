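"""Univariable two-sample MR on a synthetic study with known truth.

Simulates GWAS summary statistics for a binary exposure and outcome linked
by a true causal log-OR of 0.129 (odds ratio ~1.14), runs the instrument
pipeline (p < 5e-8 screen, LD clumping, harmonization, F > 10, Steiger),
and prints the IVW, MR-Egger, and weighted-median estimates.
"""

from mrpath import (
    SelectionConfig,
    SimulationConfig,
    SimulationTruth,
    egger,
    egger_simex,
    f_filter,
    harmonize,
    ivw,
    ld_clump,
    select_instruments,
    simulate_study,
    steiger_filter,
    weighted_median,
)
from mrpath.report import estimates_table

truth = SimulationTruth(theta=0.129)
study = simulate_study(SimulationConfig(n_snps=146, n_med_snps=0), truth,
                       seed=42)

cfg = SelectionConfig()
iv = ld_clump(select_instruments(study.exposure, cfg), study.ld, cfg)
h = harmonize(iv, study.outcome, cfg, ld=study.ld)
h, _ = f_filter(h, cfg)
h, _ = steiger_filter(h, n_exp=130_644, n_out=143_265)

fit = egger(h)
# NOME check: when I2_GX < 0.9, measurement error in the SNP-exposure
# estimates attenuates the Egger slope, so the SIMEX-corrected fit is used
egger_est = (egger_simex(h, seed=1) if fit.i2_gx < 0.9 else fit.slope)
estimates = [ivw(h), egger_est, weighted_median(h, seed=1)]
print(estimates_table(estimates, "outcome", binary_outcome=True)
      .to_string(index=False))
print(f"\nEgger intercept p = {fit.intercept_pval:.3f} "
      f"(pleiotropy test), I2_GX = {fit.i2_gx:.3f}"
      + (" -> SIMEX correction applied" if fit.i2_gx < 0.9 else ""))
print(f"True causal log-OR: {truth.theta} "
      "(the IVW and weighted-median CIs should cover it; the OR column is "
      "exp(beta)).")
print("MR-Egger trades precision for pleiotropy robustness: with instrument "
      "effects spanning a narrow range (I2_GX < 0.9) its slope is attenuated "
      "by exposure measurement error, which the SIMEX extrapolation only "
      "partly corrects; under pleiotropy-free data IVW is the estimate to "
      "read.")
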