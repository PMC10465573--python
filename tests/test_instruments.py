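"""Instrument selection, clumping, proxies, harmonization, and QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrpath.instruments import (
    HarmonizationError,
    SelectionConfig,
    compute_snp_r2,
    f_filter,
    f_statistic,
    find_proxy,
    harmonize,
    ld_clump,
    power_binary,
    select_instruments,
    steiger_filter,
)
from mrpath.sumstats import LDReference, SumStatRecord

from conftest import make_hset, make_table

CFG = SelectionConfig()


def snp_row(snp_id, pval, chrom="1", pos=1000, ea="A", oa="G", eaf=0.2,
            beta=0.1, se=0.01, **kw):
    return dict(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea,
                other_allele=oa, eaf=eaf, beta=beta, se=se, pval=pval, **kw)


class TestSelect:
    def test_threshold_strict(self):
        table = make_table([snp_row("rs1", 1e-9), snp_row("rs2", 1e-7),
                            snp_row("rs3", 5e-8)])
        kept = select_instruments(table, CFG)
        # exactly 5e-8 is excluded: the threshold is strict
        assert list(kept.data["snp_id"]) == ["rs1"]

    def test_empty_result_carries_warning(self):
        table = make_table([snp_row("rs1", 0.5)])
        kept = select_instruments(table, CFG)
        assert len(kept) == 0 and any("no variants" in d for d in kept.diagnostics)

    def test_count_matches_direct_scan(self, rng):
        """500 synthetic p-values; kept count equals a direct scan."""
        pvals = 10 ** rng.uniform(-12, 0, size=500)
        rows = [snp_row(f"rs{i}", p, pos=1000 + i) for i, p in enumerate(pvals)]
        table = make_table(rows)
        expected = int(np.sum(pvals < 5e-8))
        assert len(select_instruments(table, CFG)) == expected


class TestClump:
    def test_linked_pair_keeps_lowest_p(self):
        table = make_table([snp_row("rs1", 1e-10, pos=1_000_000),
                            snp_row("rs2", 1e-9, pos=6_000_000)])
        ld = LDReference(pairs={("rs1", "rs2"): 0.5},
                         positions={"rs1": ("1", 1_000_000),
                                    "rs2": ("1", 6_000_000)})
        kept = ld_clump(table, ld, CFG)
        assert list(kept.data["snp_id"]) == ["rs1"]

    def test_r2_below_threshold_keeps_both(self):
        table = make_table([snp_row("rs1", 1e-10, pos=1_000_000),
                            snp_row("rs2", 1e-9, pos=2_000_000)])
        ld = LDReference(pairs={("rs1", "rs2"): 0.0005},
                         positions={"rs1": ("1", 1_000_000),
                                    "rs2": ("1", 2_000_000)})
        assert len(ld_clump(table, ld, CFG)) == 2

    def test_outside_window_kept_despite_ld(self):
        far = 11_000_000 * 1000  # beyond the 10,000 kb window... use bp
        table = make_table([snp_row("rs1", 1e-10, pos=1),
                            snp_row("rs2", 1e-9, pos=1 + 10_001_000)])
        ld = LDReference(pairs={("rs1", "rs2"): 0.9},
                         positions={"rs1": ("1", 1),
                                    "rs2": ("1", 1 + 10_001_000)})
        assert len(ld_clump(table, ld, CFG)) == 2

    @staticmethod
    def _brute_force_greedy(df, r2_lookup, cfg):
        """Independent greedy re-implementation used as the oracle."""
        rows = sorted(df.itertuples(), key=lambda r: (r.pval, r.snp_id))
        kept, removed = [], set()
        for r in rows:
            if r.snp_id in removed:
                continue
            kept.append(r.snp_id)
            for other in rows:
                if other.snp_id in removed or other.snp_id in kept:
                    continue
                same = other.chrom == r.chrom
                close = abs(other.pos - r.pos) <= cfg.clump_window_kb * 1000
                if same and close and r2_lookup(r.snp_id, other.snp_id) >= cfg.clump_r2:
                    removed.add(other.snp_id)
        return kept

    def test_block_structure_vs_bruteforce(self, rng):
        """20 SNPs in 4 LD blocks of 5 -> exactly the 4 block index SNPs."""
        rows, pairs, positions = [], {}, {}
        for b in range(4):
            ids = [f"rs{b}_{i}" for i in range(5)]
            for i, sid in enumerate(ids):
                pos = b * 20_000_000 + i * 1000 + 1
                rows.append(snp_row(sid, float(rng.uniform(1e-12, 1e-8)),
                                    pos=pos))
                positions[sid] = ("1", pos)
            for i in range(5):
                for j in range(i + 1, 5):
                    pairs[(ids[i], ids[j])] = 0.7
        table = make_table(rows)
        ld = LDReference(pairs=pairs, positions=positions)
        kept = ld_clump(table, ld, CFG)
        assert len(kept) == 4
        oracle = self._brute_force_greedy(table.data, ld.r2, CFG)
        assert sorted(kept.data["snp_id"]) == sorted(oracle)
        # pairwise independence of the survivors
        ids = list(kept.data["snp_id"])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                if positions[a][0] == positions[b][0] and \
                        abs(positions[a][1] - positions[b][1]) <= CFG.clump_window_kb * 1000:
                    assert ld.r2(a, b) < CFG.clump_r2

    def test_missing_ld_policies(self):
        table = make_table([snp_row("rs1", 1e-10, pos=1000),
                            snp_row("rs_unknown", 1e-9, pos=2000)])
        ld = LDReference(positions={"rs1": ("1", 1000)})
        kept = ld_clump(table, ld, CFG)
        assert len(kept) == 2  # default policy: keep as independent
        drop_cfg = SelectionConfig(missing_ld_policy="drop")
        kept2 = ld_clump(table, ld, drop_cfg)
        assert list(kept2.data["snp_id"]) == ["rs1"]


class TestProxy:
    def _setup(self, r2s, positions=None):
        outcome = make_table([snp_row(s, 0.5, pos=p)
                              for s, p in (positions or
                                           {"rsA": 1000, "rsB": 2000}).items()])
        pairs = {("target", s): r for s, r in r2s.items()}
        pos = {"target": ("1", 0)}
        pos.update({s: ("1", p) for s, p in (positions or
                                             {"rsA": 1000, "rsB": 2000}).items()})
        return outcome, LDReference(pairs=pairs, positions=pos)

    def test_argmax_r2(self):
        outcome, ld = self._setup({"rsA": 0.9, "rsB": 0.85})
        assert find_proxy("target", outcome, ld, CFG) == "rsA"

    def test_boundary_strict(self):
        outcome, ld = self._setup({"rsA": 0.8})
        assert find_proxy("target", outcome, ld, CFG) is None

    def test_tie_broken_by_distance(self):
        outcome, ld = self._setup({"rsA": 0.95, "rsB": 0.95},
                                  positions={"rsA": 50_000, "rsB": 10_000})
        assert find_proxy("target", outcome, ld, CFG) == "rsB"


class TestHarmonize:
    def _pair(self, exp_kw, out_kw):
        exposure = make_table([snp_row("rs1", 1e-9, **exp_kw)])
        outcome = make_table([snp_row("rs1", 0.5, **out_kw)])
        return harmonize(exposure, outcome, CFG)

    def test_swapped_alleles_flip_beta(self):
        h = self._pair(dict(ea="A", oa="G", beta=0.1, eaf=0.2),
                       dict(ea="G", oa="A", beta=0.2, eaf=0.85))
        assert h.beta_out[0] == pytest.approx(-0.2)
        assert h.eaf_out[0] == pytest.approx(0.15)

    def test_strand_complement_match(self):
        h = self._pair(dict(ea="A", oa="G", beta=0.1),
                       dict(ea="T", oa="C", beta=0.2, eaf=0.2))
        assert h.beta_out[0] == pytest.approx(0.2)

    def test_palindromic_intermediate_maf_dropped(self):
        exposure = make_table([snp_row("rs1", 1e-9, ea="A", oa="T", eaf=0.5)])
        outcome = make_table([snp_row("rs1", 0.5, ea="A", oa="T", eaf=0.5)])
        with pytest.raises(HarmonizationError):
            harmonize(exposure, outcome, CFG)

    def test_palindromic_drop_reason_recorded(self):
        exposure = make_table([snp_row("rs1", 1e-9, ea="A", oa="T", eaf=0.5),
                               snp_row("rs2", 1e-9, ea="A", oa="G", eaf=0.2,
                                       pos=2000)])
        outcome = make_table([snp_row("rs1", 0.5, ea="A", oa="T", eaf=0.5),
                              snp_row("rs2", 0.5, ea="A", oa="G", eaf=0.2,
                                      pos=2000)])
        h = harmonize(exposure, outcome, CFG)
        dropped = h.provenance[h.provenance["status"] == "dropped"]
        assert list(dropped["detail"]) == ["palindromic-intermediate-maf"]

    def test_palindromic_low_maf_strand_inferred(self):
        """A/T SNP, eaf 0.1 vs 0.88: the only consistent configuration is a
        strand flip, so the outcome beta is negated."""
        h = self._pair(dict(ea="A", oa="T", beta=0.1, eaf=0.1),
                       dict(ea="A", oa="T", beta=0.2, eaf=0.88))
        assert h.beta_out[0] == pytest.approx(-0.2)
        assert h.eaf_out[0] == pytest.approx(0.12)

    def test_palindromic_low_maf_concordant_kept(self):
        h = self._pair(dict(ea="A", oa="T", beta=0.1, eaf=0.1),
                       dict(ea="A", oa="T", beta=0.2, eaf=0.12))
        assert h.beta_out[0] == pytest.approx(0.2)

    def test_palindromic_missing_eaf_dropped(self):
        exposure = make_table([snp_row("rs1", 1e-9, ea="C", oa="G", eaf=0.1)])
        outcome = make_table([snp_row("rs1", 0.5, ea="C", oa="G", eaf=None)])
        with pytest.raises(HarmonizationError):
            harmonize(exposure, outcome, CFG)

    def test_involution_flipping_outcome_record_is_neutral(self):
        """Swapping a non-palindromic outcome record's alleles together with
        the sign of its beta (and complementing eaf) leaves the harmonized
        numbers unchanged."""
        exposure = make_table([snp_row("rs1", 1e-9, ea="A", oa="G",
                                       beta=0.1, eaf=0.2)])
        out1 = make_table([snp_row("rs1", 0.5, ea="A", oa="G", beta=0.2,
                                   eaf=0.25)])
        out2 = make_table([snp_row("rs1", 0.5, ea="G", oa="A", beta=-0.2,
                                   eaf=0.75)])
        h1 = harmonize(exposure, out1, CFG)
        h2 = harmonize(exposure, out2, CFG)
        assert h1.beta_out[0] == pytest.approx(h2.beta_out[0], abs=1e-15)
        assert h1.eaf_out[0] == pytest.approx(h2.eaf_out[0], abs=1e-15)

    def test_proxy_substitution(self):
        exposure = make_table([snp_row("rs1", 1e-9, pos=1000, eaf=0.2)])
        outcome = make_table([snp_row("rs_proxy", 0.5, pos=2000, beta=0.3,
                                      eaf=0.25)])
        ld = LDReference(pairs={("rs1", "rs_proxy"): 0.95},
                         positions={"rs1": ("1", 1000),
                                    "rs_proxy": ("1", 2000)})
        h = harmonize(exposure, outcome, CFG, ld=ld)
        assert h.beta_out[0] == pytest.approx(0.3)
        assert h.provenance.iloc[0]["status"] == "proxy"

    def test_kept_plus_dropped_equals_input(self):
        exposure = make_table([
            snp_row("rs1", 1e-9, ea="A", oa="G", eaf=0.2),
            snp_row("rs2", 1e-9, ea="A", oa="T", eaf=0.5, pos=2000),
            snp_row("rs3", 1e-9, ea="C", oa="G", eaf=0.1, pos=3000),
            snp_row("rs4", 1e-9, ea="A", oa="G", eaf=0.2, pos=4000),
        ])
        outcome = make_table([
            snp_row("rs1", 0.5, ea="A", oa="G", eaf=0.2),
            snp_row("rs2", 0.5, ea="A", oa="T", eaf=0.5, pos=2000),
            snp_row("rs3", 0.5, ea="C", oa="G", eaf=0.12, pos=3000),
        ])
        h = harmonize(exposure, outcome, CFG)
        assert len(h.provenance) == 4
        dropped = h.provenance["status"] == "dropped"
        assert dropped.sum() + len(h) == 4
        assert (h.provenance.loc[dropped, "detail"] != "").all()


class TestStrength:
    def test_r2_continuous_plugin(self):
        rec = SumStatRecord("rs1", "A", "G", beta=0.1, se=0.01, pval=1e-9,
                            eaf=0.5)
        r2, method = compute_snp_r2(rec, "continuous")
        assert r2 == pytest.approx(2 * 0.25 * 0.01) and method == "eaf"

    def test_r2_zero_beta(self):
        rec = SumStatRecord("rs1", "A", "G", beta=0.0, se=0.01, pval=0.9,
                            eaf=0.3)
        assert compute_snp_r2(rec, "continuous")[0] == 0.0

    def test_r2_z_fallback(self):
        rec = SumStatRecord("rs1", "A", "G", beta=0.1, se=0.01, pval=1e-9,
                            n=10_000)
        r2, method = compute_snp_r2(rec, "continuous")
        assert r2 == pytest.approx(100 / 10100) and method == "z"

    def test_r2_no_inputs_errors(self):
        rec = SumStatRecord("rs1", "A", "G", beta=0.1, se=0.01, pval=1e-9)
        with pytest.raises(ValueError):
            compute_snp_r2(rec, "continuous")

    def test_f_statistic_plugin_and_boundary(self):
        rec = SumStatRecord("rs1", "A", "G", beta=0.1, se=0.01, pval=1e-9)
        assert f_statistic(rec) == pytest.approx(100.0)
        # a SNP exactly at the threshold is dropped: the retention rule is strict
        h = make_hset([0.02, 0.2], [0.01, 0.01], [0.0, 0.0], [0.01, 0.01])
        kept, f = f_filter(h, SelectionConfig(f_min=4.0))
        assert kept.snp_ids == ["rs2"]
        assert f[0] == 4.0

    def test_f_agrees_with_r2_form(self, rng):
        """(beta/se)^2 vs (n-2) r2/(1-r2) with the z-based r2, n >= 1e4."""
        for _ in range(20):
            n = int(rng.integers(10_000, 10**6))
            beta = rng.normal(0, 0.05)
            se = rng.uniform(0.002, 0.02)
            rec = SumStatRecord("rs", "A", "G", beta=beta, se=se, pval=0.5, n=n)
            f1 = f_statistic(rec)
            r2, _ = compute_snp_r2(rec, "binary")
            f2 = (n - 2) * r2 / (1 - r2)
            assert f2 == pytest.approx(f1, rel=0.05)


class TestSteiger:
    def test_forward_kept_reverse_dropped(self):
        h = make_hset([0.1, 0.01], [0.005, 0.005], [0.02, 0.1],
                      [0.005, 0.005])
        kept, st_out = steiger_filter(h, 100_000, 100_000)
        assert kept.snp_ids == ["rs1"]
        assert list(st_out.steiger_keep) == [True, False]

    def test_equal_r2_kept(self):
        h = make_hset([0.1], [0.005], [0.1], [0.005])
        kept, _ = steiger_filter(h, 100_000, 100_000)
        assert len(kept) == 1

    def test_causal_chain_never_filtered_noiseless(self, rng):
        """With |theta| < 1, no outcome noise, and equal sample sizes, the
        outcome r2 of a mediated SNP is strictly smaller, so Steiger keeps
        every instrument."""
        theta = 0.6
        bx = rng.normal(0, 0.1, 50)
        h = make_hset(bx, np.full(50, 0.01), theta * bx, np.full(50, 0.01))
        kept, _ = steiger_filter(h, 50_000, 50_000)
        assert len(kept) == 50

    def test_reverse_causal_snp_removed_monte_carlo(self, rng):
        """An outcome-first SNP (induced exposure effect half the outcome
        effect) is removed in > 95% of replicates at n = 1e5."""
        n = 100_000
        se = 1.0 / np.sqrt(2 * 0.3 * 0.7 * n)
        removed = 0
        reps = 200
        for _ in range(reps):
            o = 0.08
            bx = 0.5 * o + se * rng.standard_normal()
            by = o + se * rng.standard_normal()
            h = make_hset([bx, 0.1], [se, se], [by, 0.01], [se, se])
            kept, _ = steiger_filter(h, n, n)
            if "rs1" not in kept.snp_ids:
                removed += 1
        assert removed / reps > 0.95


class TestPower:
    def test_null_or_gives_alpha(self):
        assert power_binary(10**5, 0.3, 0.02, 1.0) == pytest.approx(0.05)

    def test_monotone_in_n_to_one(self):
        ns = [10**3, 10**4, 10**5, 10**6, 10**8]
        powers = [power_binary(n, 0.3, 0.02, 1.1) for n in ns]
        assert all(b >= a for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.999

    def test_matches_simulation(self, rng):
        """Formula vs Monte-Carlo rejection rate of the IVW z-test under a
        matched generative model (within +-0.03, 2000 replicates)."""
        n, k, r2_sum, or_alt = 10**5, 0.3, 0.02, 1.1
        L = 20
        maf = np.full(L, 0.25)
        # instrument effects scaled so total explained variance is r2_sum
        bx = np.sqrt(r2_sum / (L * 2 * maf * (1 - maf)))
        se_y = 1.0 / np.sqrt(2 * maf * (1 - maf) * n * k * (1 - k))
        theta = np.log(or_alt)
        reps = 2000
        by = theta * bx + se_y * rng.standard_normal((reps, L))
        w = 1.0 / se_y**2
        denom = np.sum(w * bx**2)
        est = (w * bx * by).sum(axis=1) / denom
        z = est * np.sqrt(denom)
        rate = float(np.mean(np.abs(z) > stats.norm.ppf(0.975)))
        assert rate == pytest.approx(power_binary(n, k, r2_sum, or_alt),
                                     abs=0.03)
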