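"""Selection thresholds, clumping vs an independent oracle, harmonization
case rules, and instrument-strength arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from helpers import greedy_clump_oracle
from mrpipe.exceptions import ValidationError
from mrpipe.instruments import (clump, harmonize, instrument_strength,
                                mr_power, select_candidates)
from mrpipe.sumstats import CANONICAL_COLUMNS, LdTable, SumstatsTable


def table_from_rows(rows, trait="taxon"):
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    return SumstatsTable(trait, "continuous", df)


def snp_row(snp, pval=1e-6, eaf=0.3, chrom="1", pos=1_000_000, ea="A",
            oa="G", beta=0.1, se=0.012, n=13_266):
    return dict(snp=snp, chr=chrom, pos=pos, ea=ea, oa=oa, eaf=eaf,
                beta=beta, se=se, pval=pval, n=n)


class TestSelectCandidates:
    def test_pvalue_screen(self):
        t = table_from_rows([snp_row("rs1", 1e-6), snp_row("rs2", 2e-5),
                             snp_row("rs3", 1e-4)])
        kept = select_candidates(t, p_thresh=1e-5, maf_min=0.01)
        assert list(kept.records["snp"]) == ["rs1"]

    def test_maf_boundary_is_exclusive(self):
        """A SNP at exactly MAF = 0.01 is removed (the rule is <=)."""
        t = table_from_rows([snp_row("rs1", eaf=0.99),
                             snp_row("rs2", eaf=0.985)])
        kept = select_candidates(t)
        assert list(kept.records["snp"]) == ["rs2"]

    def test_missing_eaf_is_kept(self):
        t = table_from_rows([snp_row("rs1", eaf=np.nan)])
        assert len(select_candidates(t)) == 1

    def test_empty_table(self):
        t = table_from_rows([])
        assert len(select_candidates(t)) == 0


class TestClump:
    def test_hand_example(self):
        """Index SNP absorbs the r2=0.5 neighbour but not the r2=0.0005 one."""
        t = table_from_rows([snp_row("rs1", 1e-8, pos=1_000_000),
                             snp_row("rs2", 1e-7, pos=1_100_000),
                             snp_row("rs3", 1e-6, pos=1_200_000)])
        ld = LdTable({("rs1", "rs2"): 0.5, ("rs1", "rs3"): 0.0005})
        kept = clump(t, ld)
        assert sorted(kept.records["snp"]) == ["rs1", "rs3"]

    def test_no_ld_retains_all(self):
        t = table_from_rows([snp_row(f"rs{i}", pos=1_000_000 + i * 1000)
                             for i in range(5)])
        assert len(clump(t, LdTable())) == 5

    def test_window_limits_discard(self):
        """Strong LD outside the physical window does not clump."""
        t = table_from_rows([snp_row("rs1", 1e-8, pos=1_000_000),
                             snp_row("rs2", 1e-6, pos=21_000_001)])
        ld = LdTable({("rs1", "rs2"): 0.9})
        assert len(clump(t, ld, window_kb=10_000)) == 2

    def test_output_in_genomic_order(self):
        t = table_from_rows([
            snp_row("rs1", 1e-6, chrom="2", pos=500),
            snp_row("rs2", 1e-8, chrom="1", pos=900),
            snp_row("rs3", 1e-7, chrom="1", pos=100)])
        kept = clump(t, LdTable())
        assert list(kept.records["snp"]) == ["rs3", "rs2", "rs1"]

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(st.data())
    def test_matches_exhaustive_oracle_on_small_panels(self, data):
        """Greedy clumping agrees with an independently coded scan on
        random panels of up to 12 SNPs, and every discarded SNP is in
        high LD with a better-p kept SNP within the window."""
        n = data.draw(st.integers(2, 12))
        pos = data.draw(st.lists(st.integers(1, 30_000_000), min_size=n,
                                 max_size=n, unique=True))
        pvals = data.draw(st.lists(
            st.floats(1e-12, 1e-5, allow_nan=False), min_size=n, max_size=n))
        rows = [snp_row(f"rs{i:02d}", pvals[i], chrom="1", pos=pos[i])
                for i in range(n)]
        ld = LdTable()
        for i in range(n):
            for k in range(i + 1, n):
                if data.draw(st.booleans()):
                    ld.add(f"rs{i:02d}", f"rs{k:02d}",
                           data.draw(st.floats(0, 1)))
        t = table_from_rows(rows)
        kept = clump(t, ld, r2_thresh=0.001, window_kb=10_000)
        kept_ids = sorted(kept.records["snp"])
        assert kept_ids == greedy_clump_oracle(t.records, ld, 0.001, 10_000_000)
        # subset + justification property
        kept_rows = {r.snp: r for r in kept.records.itertuples(index=False)}
        pmap = dict(zip(t.records["snp"], t.records["pval"]))
        for row in t.records.itertuples(index=False):
            if row.snp in kept_rows:
                continue
            assert any(
                abs(k.pos - row.pos) <= 10_000_000
                and ld.r2(k.snp, row.snp) >= 0.001
                and (pmap[k.snp], k.snp) < (row.pval, row.snp)
                for k in kept_rows.values())


def outcome_table(rows):
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    return SumstatsTable("pe", "binary", df, case_fraction=0.0344)


class TestHarmonize:
    def test_swapped_alleles_flip_beta(self):
        exp = table_from_rows([snp_row("rs1", ea="A", oa="G", beta=0.1)])
        out = outcome_table([snp_row("rs1", ea="G", oa="A", beta=0.05,
                                     eaf=0.7)])
        h = harmonize(exp, out)
        row = h.pairs.iloc[0]
        assert row["action"] == "flipped"
        assert row["beta_out"] == -0.05
        assert row["eaf_out"] == pytest.approx(0.3)

    def test_complementary_strand_resolved(self):
        """Outcome reported on the opposite strand (T/C vs A/G) matches
        after complementing."""
        exp = table_from_rows([snp_row("rs1", ea="A", oa="G", beta=0.1)])
        out = outcome_table([snp_row("rs1", ea="T", oa="C", beta=0.05)])
        h = harmonize(exp, out)
        assert h.pairs.iloc[0]["action"] == "kept"
        assert h.pairs.iloc[0]["beta_out"] == 0.05

    def test_palindromic_opposite_sides_flipped(self):
        exp = table_from_rows([snp_row("rs1", ea="A", oa="T", eaf=0.20,
                                       beta=0.1)])
        out = outcome_table([snp_row("rs1", ea="A", oa="T", eaf=0.79,
                                     beta=0.05)])
        h = harmonize(exp, out)
        row = h.pairs.iloc[0]
        assert row["action"] == "flipped"
        assert row["beta_out"] == -0.05
        assert row["eaf_out"] == pytest.approx(0.21)

    def test_palindromic_ambiguous_dropped(self):
        exp = table_from_rows([snp_row("rs1", ea="C", oa="G", eaf=0.2)])
        out = outcome_table([snp_row("rs1", ea="C", oa="G", eaf=0.50)])
        h = harmonize(exp, out)
        assert h.is_empty
        assert h.audit.iloc[0]["action"] == "dropped_palindromic"

    def test_incompatible_and_missing_recorded(self):
        exp = table_from_rows([snp_row("rs1", ea="A", oa="G"),
                               snp_row("rs2", ea="A", oa="G", pos=2_000_000)])
        out = outcome_table([snp_row("rs1", ea="A", oa="C")])
        h = harmonize(exp, out)
        assert h.is_empty
        actions = dict(zip(h.audit["snp"], h.audit["action"]))
        assert actions == {"rs1": "dropped_incompatible",
                           "rs2": "dropped_missing"}

    def test_involution(self):
        """Harmonizing already-harmonized tables changes nothing."""
        exp = table_from_rows([
            snp_row("rs1", ea="A", oa="G", beta=0.1, eaf=0.3),
            snp_row("rs2", ea="A", oa="T", beta=-0.2, eaf=0.2,
                    pos=2_000_000)])
        out = outcome_table([
            snp_row("rs1", ea="G", oa="A", beta=0.05, eaf=0.7),
            snp_row("rs2", ea="A", oa="T", beta=0.03, eaf=0.25,
                    pos=2_000_000)])
        h1 = harmonize(exp, out)
        out2_rows = []
        for r in h1.pairs.itertuples(index=False):
            out2_rows.append(snp_row(r.snp, ea=r.ea, oa=r.oa, beta=r.beta_out,
                                     eaf=r.eaf_out, pos=r.pos,
                                     se=r.se_out))
        h2 = harmonize(exp, outcome_table(out2_rows))
        assert np.allclose(h1.pairs["beta_out"], h2.pairs["beta_out"])
        assert np.allclose(h1.pairs["eaf_out"], h2.pairs["eaf_out"])

    def test_joint_outcome_flip_is_invisible(self):
        """Swapping the outcome's allele labels and negating its beta gives
        the same harmonized (gamma, Gamma) pairs."""
        exp = table_from_rows([snp_row("rs1", ea="A", oa="G", beta=0.1)])
        out_a = outcome_table([snp_row("rs1", ea="A", oa="G", beta=0.05,
                                       eaf=0.3)])
        out_b = outcome_table([snp_row("rs1", ea="G", oa="A", beta=-0.05,
                                       eaf=0.7)])
        ha, hb = harmonize(exp, out_a), harmonize(exp, out_b)
        assert hb.pairs["beta_out"].iloc[0] == pytest.approx(
            ha.pairs["beta_out"].iloc[0])
        assert hb.pairs["eaf_out"].iloc[0] == pytest.approx(
            ha.pairs["eaf_out"].iloc[0])


class TestStrength:
    def test_printed_formula(self, two_snp_set):
        """R2 = 0.01, N = 13,266, K = 13 gives F = 10.30 to 2 dp."""
        r2, n, k = 0.01, 13_266, 13
        f = r2 * (n - 1 - k) / ((1 - r2) * k)
        assert round(f, 2) == 10.30
        # and the operation satisfies the identity exactly
        res = instrument_strength(two_snp_set, n=13_266)
        assert res.f_stat == pytest.approx(
            res.r2_total * (res.n - 1 - res.k)
            / ((1 - res.r2_total) * res.k), rel=0, abs=0)

    def test_single_snp_variance_explained(self):
        from helpers import make_hset
        h = make_hset(bx=[0.1], sx=[0.01], by=[0.0], sy=[0.1],
                      eaf_exp=[0.25])
        res = instrument_strength(h, n=1000)
        assert res.r2_total == pytest.approx(2 * 0.25 * 0.75 * 0.01)

    def test_zero_beta_gives_zero_f(self):
        from helpers import make_hset
        h = make_hset(bx=[0.0], sx=[0.01], by=[0.0], sy=[0.1],
                      eaf_exp=[0.25])
        res = instrument_strength(h, n=1000)
        assert res.f_stat == 0.0

    def test_insufficient_sample_size(self, two_snp_set):
        with pytest.raises(ValidationError, match="sample size"):
            instrument_strength(two_snp_set, n=3)


class TestPower:
    def test_null_limit(self):
        assert mr_power(166_401, 0.0344, 0.002, theta=0.0) == pytest.approx(
            0.025, abs=1e-3)

    def test_study_scale_example(self):
        """Power for OR = 0.76 at the study's outcome size and R2 = 0.002."""
        v = 5731 / 166_401
        power = mr_power(166_401, v, 0.002, theta=np.log(0.76))
        ncp = abs(np.log(0.76)) * np.sqrt(166_401 * 0.002 * v * (1 - v))
        assert power == pytest.approx(stats.norm.cdf(ncp - 1.959964), abs=1e-6)
        assert round(power, 2) == 0.15

    def test_monotone_in_theta_and_n(self):
        p = [mr_power(100_000, 0.05, 0.01, theta=t) for t in (0.0, 0.1, 0.2)]
        assert p[0] < p[1] < p[2]
        q = [mr_power(n, 0.05, 0.01, theta=0.1) for n in (50_000, 200_000)]
        assert q[0] < q[1]

    def test_bad_r2(self):
        with pytest.raises(ValidationError):
            mr_power(1000, 0.1, 0.0, theta=0.1)
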