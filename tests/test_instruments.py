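"""Instrument selection, clumping, proxies, harmonization, strength."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit.instruments import (
    HarmonizationPolicy,
    NoInstrumentsError,
    clump,
    find_proxy,
    harmonize,
    instrument_strength,
    is_palindromic,
    select_instruments,
)
from mrkit.sumstats import (
    LDTable,
    SummaryStatsTable,
    SumstatsValidationError,
    VariantAssociation,
)

from conftest import random_table


def _table(rows, trait_id="toy", **meta):
    return SummaryStatsTable.from_records(trait_id, [VariantAssociation(**r) for r in rows], **meta)


def _row(snp, beta=0.1, se=0.02, pval=1e-9, eaf=0.3, ea="A", oa="G", **kw):
    return dict(snp=snp, effect_allele=ea, other_allele=oa, beta=beta, se=se,
                pval=pval, eaf=eaf, **kw)


class TestSelect:
    def test_none_pass_when_all_above_threshold(self):
        t = _table([_row("rs1", pval=1e-7), _row("rs2", pval=1e-7)])
        assert len(select_instruments(t, 5e-8)) == 0

    def test_threshold_is_strict(self):
        t = _table([_row("rs1", pval=5e-8), _row("rs2", pval=4.9e-8)])
        assert select_instruments(t, 5e-8).snps == ["rs2"]

    def test_fixture_fully_retained(self, instrument_table):
        assert len(select_instruments(instrument_table, 5e-8)) == 23

    def test_matches_linear_scan(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, n=40)
        expected = sorted(s for s, p in zip(t.df["snp"], t.df["pval"]) if p < 1e-3)
        assert sorted(select_instruments(t, 1e-3).snps) == expected


def _brute_force_clump(table, ld, r2_max, window_kb):
    """Independent greedy reference: explicit p-ordered scan."""
    rows = sorted(table.records(), key=lambda r: (r.pval, r.snp))
    kept = []
    for r in rows:
        ok = True
        for a in kept:
            if r.chrom is not None and a.chrom is not None and r.chrom != a.chrom:
                continue
            if r.pos is not None and a.pos is not None and abs(r.pos - a.pos) > window_kb * 1000:
                continue
            r2 = ld.r2(r.snp, a.snp) if ld else None
            if (r2 or 0.0) >= r2_max:
                ok = False
        if ok:
            kept.append(r)
    return sorted(x.snp for x in kept)


class TestClump:
    def test_single_snp_survives(self):
        t = _table([_row("rs1", chrom="1", pos=100)])
        assert clump(t, None).snps == ["rs1"]

    def test_linked_pair_keeps_lower_p(self):
        t = _table([_row("rs1", pval=1e-9, chrom="1", pos=1000),
                    _row("rs2", pval=1e-8, chrom="1", pos=2000)])
        ld = LDTable(df=pd.DataFrame({"snp_a": ["rs1"], "snp_b": ["rs2"], "r2": [0.5]}))
        assert clump(t, ld, r2_max=0.001, window_kb=10_000).snps == ["rs1"]

    def test_matches_brute_force_on_toy_panel(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, n=10)
        pairs = [(a, b) for i, a in enumerate(t.snps) for b in t.snps[i + 1:]]
        ld = LDTable(df=pd.DataFrame(
            {"snp_a": [a for a, _ in pairs], "snp_b": [b for _, b in pairs],
             "r2": rng.uniform(0, 1, len(pairs)) ** 2}))
        got = sorted(clump(t, ld, r2_max=0.1, window_kb=10_000).snps)
        assert got == _brute_force_clump(t, ld, 0.1, 10_000)

    def test_output_has_no_linked_within_window_pair(self):
        rng = np.random.default_rng(11)
        t = random_table(rng, n=15)
        pairs = [(a, b) for i, a in enumerate(t.snps) for b in t.snps[i + 1:]]
        ld = LDTable(df=pd.DataFrame(
            {"snp_a": [a for a, _ in pairs], "snp_b": [b for _, b in pairs],
             "r2": rng.uniform(0, 0.8, len(pairs))}))
        kept = clump(t, ld, r2_max=0.2, window_kb=10_000)
        for i, a in enumerate(kept.records()):
            for b in kept.records()[i + 1:]:
                if a.chrom == b.chrom and abs(a.pos - b.pos) <= 10_000_000:
                    assert (ld.r2(a.snp, b.snp) or 0.0) < 0.2

    def test_missing_ld_pairs_treated_as_unlinked(self):
        t = _table([_row("rs1", pval=1e-9, chrom="1", pos=1000),
                    _row("rs2", pval=1e-8, chrom="1", pos=2000)])
        assert sorted(clump(t, None).snps) == ["rs1", "rs2"]

    def test_bad_r2_max_rejected(self):
        t = _table([_row("rs1")])
        with pytest.raises(ValueError):
            clump(t, None, r2_max=1.5)


class TestPalindromic:
    @pytest.mark.parametrize("ea, oa, expected", [
        ("C", "G", True), ("A", "T", True), ("G", "C", True), ("T", "A", True),
        ("T", "C", False), ("A", "G", False), ("C", "T", False),
    ])
    def test_truth_table(self, ea, oa, expected):
        assert is_palindromic(ea, oa) is expected

    def test_invalid_allele_rejected(self):
        with pytest.raises(SumstatsValidationError):
            is_palindromic("A", "N")

    def test_fixture_screen_flags_the_two_cg_snps(self, instrument_table):
        flagged = {r.snp for r in instrument_table.records()
                   if is_palindromic(r.effect_allele, r.other_allele)}
        assert flagged == {"rs28558138", "rs62401797"}


class TestFindProxy:
    def _outcome(self):
        return _table([_row("rs10"), _row("rs11"), _row("rs12")], trait_id="out")

    def test_no_ld_entries_gives_none(self):
        assert find_proxy("rs1", LDTable(), self._outcome()) is None

    def test_highest_r2_candidate_wins(self):
        ld = LDTable(df=pd.DataFrame(
            {"snp_a": ["rs1", "rs1"], "snp_b": ["rs10", "rs11"], "r2": [0.92, 0.95]}))
        assert find_proxy("rs1", ld, self._outcome(), 0.9) == ("rs11", 0.95)

    def test_threshold_is_strict(self):
        ld = LDTable(df=pd.DataFrame({"snp_a": ["rs1"], "snp_b": ["rs10"], "r2": [0.90]}))
        assert find_proxy("rs1", ld, self._outcome(), 0.9) is None

    def test_candidates_absent_from_outcome_ignored(self):
        ld = LDTable(df=pd.DataFrame({"snp_a": ["rs1"], "snp_b": ["rs99"], "r2": [0.99]}))
        assert find_proxy("rs1", ld, self._outcome(), 0.9) is None


class TestHarmonize:
    def test_swapped_alleles_flip_beta_and_frequency(self):
        exp = _table([_row("rs1", beta=0.1, eaf=0.25, ea="A", oa="G")], trait_id="exp")
        out = _table([_row("rs1", beta=0.2, eaf=0.3, ea="G", oa="A")], trait_id="out")
        h = harmonize(exp, out)
        assert h.records[0].beta_out == pytest.approx(-0.2)
        assert h.records[0].eaf_out == pytest.approx(0.7)

    def test_identity_harmonization(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, n=8)
        h = harmonize(t, t)
        assert h.exclusions == []
        for r in h.records:
            assert r.beta_out == r.beta_exp and r.eaf_out == r.eaf_exp

    def test_orientation_invariance(self):
        rng = np.random.default_rng(6)
        exp = random_table(rng, n=8, trait_id="exp")
        out = random_table(np.random.default_rng(6), n=8, trait_id="out")
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        flipped = out.df.copy()
        flipped["effect_allele"], flipped["other_allele"] = (
            out.df["other_allele"],
            out.df["effect_allele"],
        )
        flipped["beta"] = -out.df["beta"]
        flipped["eaf"] = 1 - out.df["eaf"]
        out2 = SummaryStatsTable(trait_id="out", df=flipped)
        h1, h2 = harmonize(exp, out), harmonize(exp, out2)
        for a, b in zip(h1.records, h2.records):
            assert a.beta_out == pytest.approx(b.beta_out)
            assert a.eaf_out == pytest.approx(b.eaf_out)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(8)
        exp = random_table(rng, n=10, trait_id="exp")
        out = random_table(np.random.default_rng(9), n=10, trait_id="out")
        h = harmonize(exp, out)
        exp2 = SummaryStatsTable.from_records("exp", [
            VariantAssociation(snp=r.snp, effect_allele=e.effect_allele, other_allele=e.other_allele,
                               beta=r.beta_exp, se=r.se_exp, pval=1e-9, eaf=r.eaf_exp)
            for r, e in ((r, exp.record(r.snp)) for r in h.records)])
        out2 = SummaryStatsTable.from_records("out", [
            VariantAssociation(snp=r.snp, effect_allele=e.effect_allele, other_allele=e.other_allele,
                               beta=r.beta_out, se=r.se_out, pval=1e-9, eaf=r.eaf_out)
            for r, e in ((r, exp.record(r.snp)) for r in h.records)])
        h2 = harmonize(exp2, out2)
        assert h2.exclusions == []
        for a, b in zip(h.records, h2.records):
            assert (a.snp, a.beta_out, a.eaf_out) == (b.snp, b.beta_out, b.eaf_out)

    def test_palindromic_excluded_by_default(self):
        exp = _table([_row("rs1", ea="C", oa="G"), _row("rs2")], trait_id="exp")
        out = _table([_row("rs1", ea="C", oa="G"), _row("rs2")], trait_id="out")
        h = harmonize(exp, out)
        assert ("rs1", "palindromic") in h.exclusions and h.snps == ["rs2"]

    def test_palindromic_infer_policy(self):
        # clear frequencies orient; ambiguous band excludes
        exp = _table([_row("rs1", ea="C", oa="G", beta=0.1, eaf=0.2),
                      _row("rs2", ea="A", oa="T", beta=0.1, eaf=0.5)], trait_id="exp")
        out = _table([_row("rs1", ea="C", oa="G", beta=0.3, eaf=0.8),
                      _row("rs2", ea="A", oa="T", beta=0.3, eaf=0.5)], trait_id="out")
        h = harmonize(exp, out, policy=HarmonizationPolicy(palindromic="infer"))
        # rs1 frequencies disagree in direction -> orientation flip
        assert h.records[0].beta_out == pytest.approx(-0.3)
        assert h.records[0].eaf_out == pytest.approx(0.2)
        assert ("rs2", "ambiguous_frequency") in h.exclusions

    def test_missing_without_proxy_is_audited(self):
        exp = _table([_row("rs1"), _row("rs2")], trait_id="exp")
        out = _table([_row("rs2")], trait_id="out")
        h = harmonize(exp, out)
        assert ("rs1", "missing_in_outcome_no_proxy") in h.exclusions

    def test_proxy_substitution_with_allele_map(self):
        exp = _table([_row("rs1", beta=0.1, ea="A", oa="G", eaf=0.3)], trait_id="exp")
        out = _table([_row("rs9", beta=0.4, ea="T", oa="C", eaf=0.65)], trait_id="out")
        # the C allele of rs9 travels with the A (effect) allele of rs1
        ld = LDTable(df=pd.DataFrame(
            {"snp_a": ["rs1"], "snp_b": ["rs9"], "r2": [0.95],
             "allele_a": ["A"], "allele_b_linked": ["C"]}))
        h = harmonize(exp, out, ld=ld)
        r = h.records[0]
        assert r.used_snp == "rs9" and r.proxy_r2 == 0.95
        assert r.beta_out == pytest.approx(-0.4)  # rs9 effect allele T tags G=other

    def test_proxy_without_allele_map_uses_eaf_similarity(self):
        exp = _table([_row("rs1", beta=0.1, ea="A", oa="G", eaf=0.2)], trait_id="exp")
        out = _table([_row("rs9", beta=0.4, ea="T", oa="C", eaf=0.22)], trait_id="out")
        ld = LDTable(df=pd.DataFrame({"snp_a": ["rs1"], "snp_b": ["rs9"], "r2": [0.95]}))
        h = harmonize(exp, out, ld=ld)
        assert h.records[0].beta_out == pytest.approx(0.4)
        # ambiguous when both orientations are close
        out2 = _table([_row("rs9", beta=0.4, ea="T", oa="C", eaf=0.5)], trait_id="out")
        with pytest.raises(NoInstrumentsError):
            harmonize(exp, out2, ld=ld)

    def test_no_instruments_error(self):
        exp = _table([_row("rs1")], trait_id="exp")
        out = _table([_row("rs2")], trait_id="out")
        with pytest.raises(NoInstrumentsError):
            harmonize(exp, out)


class TestInstrumentStrength:
    def test_half_maf_unit_beta(self):
        t = _table([_row("rs1", beta=1.0, eaf=0.5)])
        s = instrument_strength(t)
        assert s.total_r2 == pytest.approx(0.5)

    def test_single_published_instrument(self, instrument_table):
        s = instrument_strength(instrument_table.subset(["rs11121615"]))
        # 2 * 0.31 * 0.69 * 0.284^2
        assert s.per_snp_r2[0][1] == pytest.approx(0.0345, abs=5e-4)

    def test_total_variance_explained(self, instrument_table):
        s = instrument_strength(instrument_table)
        assert round(s.total_r2, 3) == 0.150

    def test_f_statistics_require_n(self, instrument_table):
        s = instrument_strength(instrument_table)
        assert s.total_f is None and s.mean_f is None
        s2 = instrument_strength(instrument_table, n=20_000)
        assert s2.total_f > 10 and s2.strong()
        assert len(s2.per_snp_f) == 23

    def test_f_monotone_in_n(self, instrument_table):
        fs = [instrument_strength(instrument_table, n=n).total_f
              for n in (5_000, 20_000, 100_000, 400_000)]
        assert fs == sorted(fs) and fs[0] != fs[-1]

    def test_missing_eaf_fails_loudly(self):
        t = _table([dict(snp="rs1", effect_allele="A", other_allele="G",
                         beta=0.1, se=0.02, pval=1e-9, eaf=None)])
        with pytest.raises(SumstatsValidationError, match="EAF"):
            instrument_strength(t)

    @given(st.integers(0, 22))
    @settings(max_examples=10, deadline=None)
    def test_total_r2_invariant_under_allele_flip(self, idx):
        from mrkit.sumstats import varicose_instruments

        t = varicose_instruments()
        base = instrument_strength(t).total_r2
        df = t.df.copy()
        df.loc[idx, "eaf"] = 1 - df.loc[idx, "eaf"]
        df.loc[idx, "beta"] = -df.loc[idx, "beta"]
        flipped = SummaryStatsTable(trait_id=t.trait_id, df=df)
        assert instrument_strength(flipped).total_r2 == pytest.approx(base)
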