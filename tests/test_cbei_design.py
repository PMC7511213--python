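from itertools import product

import numpy as np
import pytest

from cbei.cbe_model import CbeModel, load_preset
from cbei.cbei_design import (
    find_cbei_sites,
    region_filter,
    stop_creating_codons,
    stop_creating_edits,
)
from cbei.seqcore import NucSequence, load_genetic_code

from .conftest import random_seq
from .oracles import brute_design_sites


def toy_cds_60() -> str:
    """60-nt CDS with one CAA reachable at window position 5 of a unique
    NGG-adjacent 20-nt protospacer (windows 4-8): protospacer at base 6,
    PAM AGG, edited codon 4."""
    s = list("A" * 60)
    s[0:3] = "ATG"
    s[9:12] = "CAA"
    s[25:28] = "AGG"
    s[57:60] = "TAA"
    return "".join(s)


class TestStopCreatingEdits:
    def test_caa_single_sense_edit(self, standard_code):
        assert stop_creating_edits("CAA", standard_code) == {
            ("+", frozenset({0}), "TAA")
        }

    def test_aaa_has_no_edit(self, standard_code):
        assert stop_creating_edits("AAA", standard_code) == set()

    def test_tgg_antisense_edits(self, standard_code):
        edits = stop_creating_edits("TGG", standard_code)
        assert edits == {
            ("-", frozenset({1}), "TAG"),
            ("-", frozenset({2}), "TGA"),
            ("-", frozenset({1, 2}), "TAA"),
        }

    def test_existing_stop_yields_nothing(self, standard_code):
        assert stop_creating_edits("TAA", standard_code) == set()

    def test_standard_code_exhaustive_scan_gives_four_codons(self, standard_code):
        assert stop_creating_codons(standard_code) == {"CAA", "CAG", "CGA", "TGG"}

    def test_nonstandard_code_not_hardcoded(self):
        # ciliate code (table 6): only TGA is a stop, so the convertible
        # set differs from the standard four; verify against independent
        # enumeration of every codon and every single-strand edit subset.
        code6 = load_genetic_code(6)
        expected = set()
        for codon in ("".join(c) for c in product("ACGT", repeat=3)):
            if codon in code6.stop_codons:
                continue
            for base, new in (("C", "T"), ("G", "A")):
                pos = [i for i in range(3) if codon[i] == base]
                for mask in range(1, 2 ** len(pos)):
                    subset = [p for k, p in enumerate(pos) if mask >> k & 1]
                    edited = "".join(
                        new if i in subset else codon[i] for i in range(3)
                    )
                    if edited in code6.stop_codons:
                        expected.add(codon)
        assert stop_creating_codons(code6) == expected == {"CGA", "TGG"}


class TestFindCbeiSites:
    def test_toy_cds_single_engineered_site(self, standard_code):
        model = load_preset("BE3")
        report = find_cbei_sites(NucSequence("toy", toy_cds_60()), model, standard_code, 100)
        assert report.n_sites_whole_cds == 1
        s = report.sites[0]
        assert (s.strand, s.proto_start, s.edited_codon_index) == ("+", 6, 4)
        assert (s.codon_before, s.codon_after) == ("CAA", "TAA")
        assert s.edit_positions == (5,)
        assert s.pam_seq == "AGG"
        assert s.cds_fraction == pytest.approx(10 / 60)

    def test_no_pam_match_no_sites(self, standard_code):
        model = load_preset("VRER-BE3")  # NGCG never occurs in an A/T-only CDS
        cds = NucSequence("at", "ATG" + "AAT" * 30 + "TAA")
        assert find_cbei_sites(cds, model, standard_code).n_sites_whole_cds == 0

    def test_cds_shorter_than_spacer_plus_pam(self, standard_code):
        report = find_cbei_sites(
            NucSequence("short", "ATGCAATAA"), load_preset("BE3"), standard_code
        )
        assert report.n_sites_whole_cds == 0
        assert "shorter" in report.warning

    def test_codon_before_always_one_of_the_four(self, standard_code):
        model = load_preset("BE3")
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cds = NucSequence(f"r{seed}", random_seq(rng, 900))
            rep = find_cbei_sites(cds, model, standard_code, 100)
            assert {s.codon_before for s in rep.sites} <= {"CAA", "CAG", "CGA", "TGG"}

    def test_replay_invariant(self, standard_code):
        model = load_preset("BE-PLUS")
        rng = np.random.default_rng(7)
        cds = NucSequence("r", random_seq(rng, 1200))
        rep = find_cbei_sites(cds, model, standard_code, 100)
        assert rep.sites
        L = model.spacer_len
        for s in rep.sites:
            p = s.proto_start - 1
            edited = list(cds.seq)
            for w in s.edit_positions:
                q = p + w - 1 if s.strand == "+" else p + L - w
                edited[q] = "T" if s.strand == "+" else "A"
            j = s.edited_codon_index - 1
            new_codon = "".join(edited[3 * j : 3 * j + 3])
            assert new_codon == s.codon_after
            assert new_codon in standard_code.stop_codons
            assert j < len(cds.seq) // 3 - 1

    def test_natural_terminator_not_reported(self, standard_code):
        # a CAA in the final codon slot must not count as premature
        s = list("A" * 33)
        s[0:3] = "ATG"
        s[30:33] = "CAA"  # final codon
        s[7:10] = "AGG"  # irrelevant PAM elsewhere
        model = CbeModel("wide", "NNN", "3prime", 6, 1, 6)
        rep = find_cbei_sites(NucSequence("t", "".join(s)), model, standard_code, 100)
        assert all(site.edited_codon_index < 11 for site in rep.sites)

    def test_site_containing_n_skipped(self, standard_code):
        s = toy_cds_60()
        with_n = s[:7] + "N" + s[8:]  # N inside the unique protospacer
        rep = find_cbei_sites(NucSequence("n", with_n), load_preset("BE3"), standard_code, 100)
        assert rep.n_sites_whole_cds == 0

    def test_matches_bruteforce_enumerator(self, standard_code):
        for seed, preset in [(0, "BE3"), (1, "YEE-BE3"), (2, "Cas12a-BE"), (3, "SaBE3")]:
            rng = np.random.default_rng(seed)
            model = load_preset(preset)
            cds = NucSequence("r", random_seq(rng, 600))
            rep = find_cbei_sites(cds, model, standard_code, 100)
            got = {(s.strand, s.proto_start, s.edited_codon_index) for s in rep.sites}
            assert got == brute_design_sites(cds.seq, model, standard_code)


class TestContextAnnotation:
    @pytest.mark.parametrize(
        "prev,expected_ctx,expected_rank",
        [("T", "TC", 1), ("C", "CC", 2), ("A", "AC", 3), ("G", "GC", 4)],
    )
    def test_sense_strand_context(self, prev, expected_ctx, expected_rank, standard_code):
        s = list(toy_cds_60())
        s[8] = prev  # base 5' of the stop-creating C at position 9
        if prev == "G":  # avoid creating a second NGG placement upstream
            s[7] = "T"
        rep = find_cbei_sites(
            NucSequence("t", "".join(s)), load_preset("BE3"), standard_code, 100
        )
        site = next(x for x in rep.sites if x.edited_codon_index == 4)
        assert (site.context, site.context_rank) == (expected_ctx, expected_rank)

    def test_edit_at_cds_start_has_unknown_context(self, standard_code):
        # C at position 1 of the CDS: no 5' base exists
        s = list("CAA" + "A" * 27)
        s[20:23] = "AGG"
        model = CbeModel("w1", "NGG", "3prime", 20, 1, 8)
        rep = find_cbei_sites(NucSequence("t", "".join(s)), model, standard_code, 100)
        site = next(x for x in rep.sites if x.edited_codon_index == 1)
        assert site.context_rank is None


class TestRegionFilter:
    def test_full_region_is_identity(self, standard_code):
        rep = find_cbei_sites(
            NucSequence("t", toy_cds_60()), load_preset("BE3"), standard_code, 100
        )
        out = region_filter(rep, 100)
        assert out.n_sites_in_region == rep.n_sites_whole_cds

    def test_threshold_arithmetic(self):
        from cbei.cbei_design import _make_report, CbeiSite

        site = CbeiSite(
            cbe_name="BE3", cds_id="x", spacer_seq="A" * 20, pam_seq="AGG",
            strand="+", proto_start=15, edited_codon_index=11,
            codon_before="CAA", codon_after="TAA", edit_positions=(5,),
            context="TC", context_rank=1, cds_fraction=31 / 60, annotation="",
        )
        rep = _make_report("x", "BE3", 100.0, [site])
        assert region_filter(rep, 50).n_sites_in_region == 0
        assert region_filter(rep, 52).n_sites_in_region == 1

    def test_monotone_in_region_fraction(self, standard_code, rng):
        cds = NucSequence("r", random_seq(rng, 1500))
        rep = find_cbei_sites(cds, load_preset("BE3"), standard_code, 100)
        counts = [region_filter(rep, f).n_sites_in_region for f in (10, 25, 50, 75, 100)]
        assert counts == sorted(counts)
        assert counts[-1] == rep.n_sites_whole_cds

    def test_out_of_range_fraction_rejected(self, standard_code):
        rep = find_cbei_sites(
            NucSequence("t", toy_cds_60()), load_preset("BE3"), standard_code
        )
        for bad in (0, -5, 101):
            with pytest.raises(ValueError):
                region_filter(rep, bad)
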