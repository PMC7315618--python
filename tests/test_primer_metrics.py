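"""Logo matrices, coverage tables, resolution scores and amplicon statistics."""

import math

import numpy as np
import pytest

from ampliscope import (
    BindingSite,
    DEFAULT_PRIMER_PAIR,
    MatchPolicy,
    Primer,
    amplicon_stats,
    build_pcm,
    coverage_table,
    resolution_score,
    scan_sequence,
    shared_species_subset,
)

from .conftest import make_hit


def site(acc, seq, mismatches=0, start=0, three=True):
    return BindingSite(
        accession=acc, strand="+", start=start, end=start + len(seq),
        mismatches=mismatches, three_prime_match=three, site_seq=seq,
    )


PRIMER8 = Primer("p8", "ACGTACGT")


class TestBuildPcm:
    def test_identical_sites_counted_per_column(self):
        sites = [site("a1", "ACGTACGT"), site("a2", "ACGTACGT")]
        (pcm,) = build_pcm(PRIMER8, sites, {"a1": "g", "a2": "g"})
        assert pcm.n_sequences == 2
        assert pcm.counts.loc["A", 1] == 2
        assert pcm.counts.loc["C", 2] == 2
        assert (pcm.counts.sum(axis=0) == 2).all()

    def test_final_column_split(self):
        sites = [site("a1", "ACGTACGT"), site("a2", "ACGTACGA")]
        (pcm,) = build_pcm(PRIMER8, sites, {"a1": "g", "a2": "g"})
        last = pcm.counts[8]
        assert last["T"] == 1 and last["A"] == 1

    def test_degenerate_base_goes_to_other_row(self):
        sites = [site("a1", "ACGTACNT")]
        (pcm,) = build_pcm(PRIMER8, sites, {"a1": "g"})
        assert pcm.counts.loc["other", 7] == 1
        assert (pcm.counts.sum(axis=0) == pcm.n_sequences).all()

    def test_per_accession_dedup_lowest_mismatch_then_leftmost(self):
        sites = [
            site("a1", "ACGTACGT", mismatches=1, start=5),
            site("a1", "TTTTACGT", mismatches=0, start=9),
            site("a1", "GGGGACGT", mismatches=0, start=20),
        ]
        (pcm,) = build_pcm(PRIMER8, sites, {"a1": "g"})
        assert pcm.n_sequences == 1
        assert pcm.counts.loc["T", 1] == 1  # the 0-mm leftmost site won

    def test_wrong_site_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            build_pcm(PRIMER8, [site("a1", "ACG")], {"a1": "g"})

    def test_column_conservation_on_planted_set(self, planted):
        refs, _ = planted
        policy = MatchPolicy()
        sites = []
        for e in refs:
            sites.extend(scan_sequence(DEFAULT_PRIMER_PAIR.forward, e.seq, policy, e.accession))
        for pcm in build_pcm(DEFAULT_PRIMER_PAIR.forward, sites, refs.group_of()):
            assert (pcm.counts.sum(axis=0) == pcm.n_sequences).all()


class TestCoverageTable:
    def test_planted_set_strict_coverage_is_clade_diagnostic(self, planted, planted_hits):
        refs, _ = planted
        _, relaxed = planted_hits
        policy = MatchPolicy(require_three_prime=False)
        fwd_sites, rev_sites = [], []
        for e in refs:
            fwd_sites.extend(scan_sequence(DEFAULT_PRIMER_PAIR.forward, e.seq, policy, e.accession))
            rev_sites.extend(scan_sequence(DEFAULT_PRIMER_PAIR.reverse, e.seq, policy, e.accession))
        cov = coverage_table(refs, fwd_sites, rev_sites, relaxed).table
        assert cov.loc["Culicidae", "frac_strict_amplifiable"] == 1.0
        off_target = cov.drop(index="Culicidae")
        assert (off_target["n_strict_amplifiable"] == 0).all()
        # every entry carries both priming sites by construction
        assert (cov["n_both_sites"] == cov["n_total"]).all()
        # tallies are bounded as n_strict <= n_both <= n_total
        assert (cov["n_strict_amplifiable"] <= cov["n_both_sites"]).all()
        assert (cov["n_both_sites"] <= cov["n_total"]).all()

    def test_counts_invariant_to_entry_order(self, planted, planted_hits):
        import ampliscope.reference_io as rio

        refs, _ = planted
        _, relaxed = planted_hits
        policy = MatchPolicy(require_three_prime=False)

        def build(refset):
            fwd, rev = [], []
            for e in refset:
                fwd.extend(scan_sequence(DEFAULT_PRIMER_PAIR.forward, e.seq, policy, e.accession))
                rev.extend(scan_sequence(DEFAULT_PRIMER_PAIR.reverse, e.seq, policy, e.accession))
            return coverage_table(refset, fwd, rev, relaxed).table

        reversed_refs = rio.ReferenceSet(list(refs)[::-1])
        a = build(refs).sort_index()
        b = build(reversed_refs).sort_index()
        assert a.equals(b)


class TestResolution:
    def test_two_modes_on_shared_insert(self):
        hits = [make_hit("a1", "AAAA"), make_hit("a2", "AAAA"), make_hit("a3", "CCCC")]
        species = {"a1": "s1", "a2": "s2", "a3": "s3"}
        su = resolution_score(hits, species, mode="species-unique")
        assert su.value == pytest.approx(1 / 3)
        assert (su.n_species, su.n_amplicons) == (3, 2)
        lca = resolution_score(hits, species, mode="amplicon-lca")
        assert lca.value == pytest.approx(1 / 2)

    def test_all_unique_is_one_under_both_modes(self):
        hits = [make_hit(f"a{i}", "ACGT" * (i + 1)) for i in range(4)]
        species = {f"a{i}": f"s{i}" for i in range(4)}
        for mode in ("species-unique", "amplicon-lca"):
            assert resolution_score(hits, species, mode=mode).value == 1.0

    def test_single_species_always_resolved(self):
        hits = [make_hit("a1", "AAAA"), make_hit("a1", "CCCC")]
        assert resolution_score(hits, {"a1": "s1"}).value == 1.0

    def test_merging_species_labels_never_increases_resolution(self):
        rng = np.random.default_rng(5)
        inserts = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(12)]
        hits = [make_hit(f"a{i}", ins) for i, ins in enumerate(inserts)]
        species = {f"a{i}": f"s{i % 6}" for i in range(12)}
        before = resolution_score(hits, species).value
        merged = {acc: ("s0" if sp == "s1" else sp) for acc, sp in species.items()}
        after = resolution_score(hits, merged).value
        assert after <= before + 1e-12

    def test_needs_hits(self):
        with pytest.raises(ValueError):
            resolution_score([], {})


class TestSharedSpeciesSubset:
    def test_disjoint_sets_empty(self):
        a = [make_hit("a1", "AAAA")]
        b = [make_hit("b1", "CCCC")]
        species = {"a1": "s1", "b1": "s2"}
        ra, rb = shared_species_subset(a, b, species)
        assert ra == [] and rb == []

    def test_identical_sets_unchanged(self):
        a = [make_hit("a1", "AAAA"), make_hit("a2", "CCCC")]
        species = {"a1": "s1", "a2": "s2"}
        ra, rb = shared_species_subset(a, list(a), species)
        assert ra == a and rb == a

    def test_intersection(self):
        species = {f"x{i}": f"s{i}" for i in range(1, 5)}
        a = [make_hit(f"x{i}", "A" * i) for i in (1, 2, 3)]
        b = [make_hit(f"x{i}", "C" * i) for i in (2, 3, 4)]
        ra, rb = shared_species_subset(a, b, species)
        assert {species[h.accession] for h in ra} == {"s2", "s3"}
        assert {species[h.accession] for h in rb} == {"s2", "s3"}


class TestAmpliconStats:
    def test_zero_sd_for_identical_lengths(self):
        hits = [make_hit("a1", "A" * 380), make_hit("a2", "A" * 380)]
        stats = amplicon_stats(hits, {"a1": "g", "a2": "g"})
        assert stats.loc["g", "length_mean"] == 400.0
        assert stats.loc["g", "length_sd"] == 0.0

    def test_sample_sd(self):
        hits = [make_hit("a1", "A" * 360), make_hit("a2", "A" * 400)]
        stats = amplicon_stats(hits, {"a1": "g", "a2": "g"})
        assert stats.loc["g", "length_mean"] == 400.0
        assert stats.loc["g", "length_sd"] == pytest.approx(math.sqrt(((20) ** 2 * 2) / 1))

    def test_gc_of_pure_gc_insert(self):
        hits = [make_hit("a1", "GGCC"), make_hit("a2", "GGCC")]
        stats = amplicon_stats(hits, {"a1": "g", "a2": "g"})
        assert stats.loc["g", "gc_mean"] == 1.0

    def test_planted_clades_match_generator_targets(self, planted, planted_hits):
        refs, _ = planted
        strict, _ = planted_hits
        subfam = {e.accession: e.taxon.lineage.get("subfamily") for e in refs}
        stats = amplicon_stats(strict, subfam)
        # generator draws insert lengths around 383 (short clade) and 432 (long clade)
        assert abs(stats.loc["Culicinae", "insert_length_mean"] - 383) < 15
        assert abs(stats.loc["Anophelinae", "insert_length_mean"] - 432) < 40
        assert abs(stats.loc["Culicinae", "gc_mean"] - 0.60) < 0.05
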