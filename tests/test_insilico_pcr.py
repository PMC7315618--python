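"""Degenerate matching, binding-site search and amplicon extraction."""

import numpy as np
import pytest

from ampliscope import (
    DEFAULT_PRIMER_PAIR,
    MOZZIE_D2_UNI_F,
    MOZZIE_D2_UNI_R,
    MatchPolicy,
    Primer,
    PrimerPair,
    ReferenceEntry,
    ReferenceSet,
    TaxonRecord,
    amplify,
    scan_sequence,
    score_site,
)
from ampliscope.insilico_pcr import iupac_compatible
from ampliscope.iupac import gc_fraction, reverse_complement

from .oracle import oracle_amplify, oracle_sites, random_degenerate_seq

FWD = MOZZIE_D2_UNI_F.seq  # AAGCACTCTGAATAGAGAGTC (3'-C)
REV = MOZZIE_D2_UNI_R.seq  # TGGTCCGTGTTTCAAGAC


def entry(acc, seq):
    return ReferenceEntry(
        taxon=TaxonRecord(accession=acc, species=f"Species {acc}"), seq=seq
    )


def template(insert, fwd_site=FWD, rev=REV, left="", right=""):
    """fwd site + insert + reverse-complemented reverse site, plus flanks."""
    return left + fwd_site + insert + reverse_complement(rev) + right


class TestIupacCompatible:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("R", "G", True), ("C", "T", False), ("N", "A", True), ("N", "N", True),
         ("S", "W", False), ("M", "K", False), ("M", "R", True)],
    )
    def test_set_intersection_rule(self, a, b, expected):
        assert iupac_compatible(a, b) is expected

    def test_symmetric(self):
        codes = "ACGTRYSWKMBDHVN"
        for a in codes:
            for b in codes:
                assert iupac_compatible(a, b) == iupac_compatible(b, a)


class TestScoreSite:
    def test_identity_window(self):
        assert score_site(MOZZIE_D2_UNI_F, FWD) == (0, True)

    def test_three_prime_thymine_template(self):
        # template carries 3'-T where the primer ends in C: one mismatch,
        # and the site is non-extensible
        window = FWD[:-1] + "T"
        assert score_site(MOZZIE_D2_UNI_F, window) == (1, False)

    def test_positionwise_count(self):
        primer = Primer("p", "ACGTACGT")
        assert score_site(primer, "ACGTACAA") == (2, False)
        assert score_site(primer, "ACATACGT") == (1, True)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            score_site(MOZZIE_D2_UNI_F, "ACGT")


class TestFindBindingSites:
    def test_exact_plus_strand_site(self):
        # non-palindromic primer so the reverse complement matches nowhere
        primer = Primer("p", "ACGGACGT")
        sites = scan_sequence(primer, "TT" + "ACGGACGT" + "TTT", MatchPolicy(max_mismatches=0))
        assert [(s.strand, s.start, s.end, s.mismatches) for s in sites] == [("+", 2, 10, 0)]
        assert sites[0].three_prime_match

    def test_minus_strand_site_in_forward_coordinates(self):
        primer = Primer("p", "ACGTTCGT")
        seq = "GG" + reverse_complement("ACGTTCGT") + "AA"
        sites = scan_sequence(primer, seq, MatchPolicy(max_mismatches=0))
        assert [(s.strand, s.start, s.end) for s in sites] == [("-", 2, 10)]
        # site_seq is reported in primer orientation
        assert sites[0].site_seq == "ACGTTCGT"

    def test_budget_zero_excludes_single_mismatch(self):
        primer = Primer("p", "ACGGACGT")
        assert scan_sequence(primer, "TTACGGACCTTT", MatchPolicy(max_mismatches=0)) == []
        sites = scan_sequence(primer, "TTACGGACCTTT", MatchPolicy(max_mismatches=1))
        assert [(s.start, s.mismatches) for s in sites if s.strand == "+"] == [(2, 1)]

    def test_degenerate_template_not_a_mismatch(self):
        primer = Primer("p", "ACGTACGT")
        sites = scan_sequence(primer, "AANNNNNNNNAA"[:2] + "ACGTRCGT" + "AA",
                              MatchPolicy(max_mismatches=0))
        assert any(s.strand == "+" and s.mismatches == 0 for s in sites)


class TestAmplify:
    def test_exact_construction_single_hit(self):
        insert = "ATGC" * 25
        refs = ReferenceSet([entry("t1", template(insert))])
        hits = amplify(DEFAULT_PRIMER_PAIR, refs, MatchPolicy())
        assert len(hits) == 1
        h = hits[0]
        assert h.length == len(FWD) + len(insert) + len(REV)
        assert h.insert == insert
        assert h.product == template(insert)

    def test_three_prime_mismatch_blocks_strict_amplification(self):
        # template base opposite the forward primer's 3'-C replaced by T
        insert = "ATGC" * 25
        refs = ReferenceSet([entry("t1", template(insert, fwd_site=FWD[:-1] + "T"))])
        strict = amplify(DEFAULT_PRIMER_PAIR, refs, MatchPolicy(require_three_prime=True))
        relaxed = amplify(DEFAULT_PRIMER_PAIR, refs, MatchPolicy(require_three_prime=False))
        assert strict == []
        assert len(relaxed) == 1

    def test_two_forward_sites_two_hits(self):
        insert = "ATGC" * 10
        seq = FWD + "ATGC" * 5 + FWD + insert + reverse_complement(REV)
        refs = ReferenceSet([entry("t1", seq)])
        hits = amplify(DEFAULT_PRIMER_PAIR, refs, MatchPolicy())
        assert len(hits) == 2
        assert sorted(h.fwd_site.start for h in hits) == [0, len(FWD) + 20]

    def test_max_length_cap(self):
        insert = "ATGC" * 600  # 2400 nt insert -> product over the 2000 cap
        refs = ReferenceSet([entry("t1", template(insert))])
        assert amplify(DEFAULT_PRIMER_PAIR, refs, MatchPolicy()) == []
        long_policy = MatchPolicy(max_amplicon_length=3000)
        assert len(amplify(DEFAULT_PRIMER_PAIR, refs, long_policy)) == 1

    def test_insert_and_gc_consistent(self, planted_hits):
        strict, _ = planted_hits
        for h in strict:
            nf, nr = len(FWD), len(REV)
            assert h.insert == h.product[nf : len(h.product) - nr]
            assert h.gc == pytest.approx(gc_fraction(h.insert))
            assert len(h.insert) == h.length - nf - nr


class TestOracleEquivalence:
    def test_sites_match_brute_force(self):
        rng = np.random.default_rng(11)
        policy = MatchPolicy(max_mismatches=5, require_three_prime=False)
        for _ in range(40):
            seq = random_degenerate_seq(rng, max_len=300)
            for primer in (MOZZIE_D2_UNI_F, MOZZIE_D2_UNI_R):
                engine = {
                    (s.strand, s.start, s.end, s.mismatches, s.three_prime_match)
                    for s in scan_sequence(primer, seq, policy)
                }
                assert engine == set(oracle_sites(primer.seq, seq, 5))

    def test_products_match_brute_force(self):
        rng = np.random.default_rng(12)
        for require3 in (True, False):
            policy = MatchPolicy(require_three_prime=require3)
            for _ in range(30):
                insert = random_degenerate_seq(rng, max_len=150)
                seq = random_degenerate_seq(rng, max_len=80) + FWD + insert
                seq += reverse_complement(REV) + random_degenerate_seq(rng, max_len=80)
                refs = ReferenceSet([entry("x", seq)])
                hits = amplify(DEFAULT_PRIMER_PAIR, refs, policy)
                engine = {
                    (min(h.fwd_site.start, h.rev_site.start),
                     max(h.fwd_site.end, h.rev_site.end),
                     h.fwd_site.strand, h.product)
                    for h in hits
                }
                assert engine == oracle_amplify(FWD, REV, seq, 5, require3, 2000)


class TestProperties:
    def test_strand_symmetry(self, planted):
        refs, _ = planted
        policy = MatchPolicy()
        fwd_products = sorted(h.product for h in amplify(DEFAULT_PRIMER_PAIR, refs, policy))
        flipped = ReferenceSet(
            ReferenceEntry(taxon=e.taxon, seq=reverse_complement(e.seq)) for e in refs
        )
        rev_products = sorted(h.product for h in amplify(DEFAULT_PRIMER_PAIR, flipped, policy))
        assert fwd_products == rev_products

    def test_tightening_policy_never_adds_hits(self):
        rng = np.random.default_rng(21)
        base = MatchPolicy(max_mismatches=5, require_three_prime=False,
                           max_amplicon_length=2000)
        tighter = [
            MatchPolicy(max_mismatches=3, require_three_prime=False),
            MatchPolicy(max_mismatches=5, require_three_prime=True),
            MatchPolicy(max_mismatches=5, require_three_prime=False,
                        max_amplicon_length=300),
        ]
        for i in range(15):
            seq = (random_degenerate_seq(rng, max_len=60) + FWD
                   + random_degenerate_seq(rng, max_len=200)
                   + reverse_complement(REV) + random_degenerate_seq(rng, max_len=60))
            refs = ReferenceSet([entry(f"s{i}", seq)])

            def keyset(policy):
                return {
                    (h.fwd_site.start, h.rev_site.start, h.fwd_site.strand, h.length)
                    for h in amplify(DEFAULT_PRIMER_PAIR, refs, policy)
                }

            base_keys = keyset(base)
            for policy in tighter:
                assert keyset(policy) <= base_keys

    def test_primer_validation(self):
        with pytest.raises(ValueError, match="minimum"):
            Primer("short", "ACGT")
        with pytest.raises(ValueError, match="distinct"):
            PrimerPair(Primer("p", "ACGTACGT"), Primer("p", "TTTTACGT"))
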