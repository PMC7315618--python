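"""Coverage tables, sequence-logo matrices, taxonomic resolution and amplicon stats.

These are the summaries a primer-evaluation run reports per taxon group:
how many reference entries carry both priming sites, how many are strictly
amplifiable under the 3'-anchor criterion, the per-position base counts at
each priming site (the matrix behind a sequence logo), what fraction of
species are unambiguously identifiable from their amplicon sequences, and
length/GC statistics of the predicted products.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .insilico_pcr import AmpliconHit, BindingSite, Primer

__all__ = [
    "PositionCountMatrix",
    "CoverageTable",
    "ResolutionScore",
    "build_pcm",
    "coverage_table",
    "resolution_score",
    "shared_species_subset",
    "amplicon_stats",
    "plot_logo",
]

PCM_ROWS = ("A", "C", "G", "T", "other")


@dataclasses.dataclass(frozen=True)
class PositionCountMatrix:
    """Integer base counts per primer position for one taxon group.

    Rows A/C/G/T plus an ``other`` row for degenerate template bases, so
    every column sums to ``n_sequences`` exactly (no fractional allocation).
    Columns are primer positions 5'->3'.
    """

    primer_name: str
    group: str
    counts: pd.DataFrame
    n_sequences: int

    def frequencies(self) -> pd.DataFrame:
        if self.n_sequences == 0:
            return self.counts.astype(float)
        return self.counts / self.n_sequences


def _dedupe_sites(sites: Iterable[BindingSite]) -> list[BindingSite]:
    """One site per accession: lowest mismatch count, then leftmost start."""
    best: dict[str, BindingSite] = {}
    for site in sites:
        cur = best.get(site.accession)
        if cur is None or (site.mismatches, site.start) < (cur.mismatches, cur.start):
            best[site.accession] = site
    return list(best.values())


def build_pcm(
    primer: Primer,
    sites: Iterable[BindingSite],
    group_of: Mapping[str, str | None],
) -> list[PositionCountMatrix]:
    """Per-group position count matrices from binding sites of one primer.

    Sites are deduplicated to one per accession (lowest mismatches, then
    leftmost) so entries with several candidate windows do not dominate the
    logo.  ``site_seq`` is already in primer orientation, so column ``j``
    counts the template base opposite primer position ``j``.
    """
    length = len(primer)
    per_group: dict[str, list[BindingSite]] = defaultdict(list)
    for site in _dedupe_sites(sites):
        if len(site.site_seq) != length:
            raise ValueError(
                f"site length {len(site.site_seq)} != primer length {length} "
                f"for accession {site.accession!r}"
            )
        label = group_of.get(site.accession) or "ungrouped"
        per_group[label].append(site)
    matrices = []
    for label in sorted(per_group):
        group_sites = per_group[label]
        counts = np.zeros((len(PCM_ROWS), length), dtype=int)
        row_index = {base: i for i, base in enumerate(PCM_ROWS)}
        for site in group_sites:
            for j, base in enumerate(site.site_seq):
                counts[row_index.get(base, row_index["other"]), j] += 1
        matrices.append(
            PositionCountMatrix(
                primer_name=primer.name,
                group=label,
                counts=pd.DataFrame(
                    counts, index=list(PCM_ROWS), columns=range(1, length + 1)
                ),
                n_sequences=len(group_sites),
            )
        )
    return matrices


@dataclasses.dataclass
class CoverageTable:
    """Per-group amplifiability tallies plus per-primer mismatch histograms.

    ``table`` rows (indexed by group label): n_total, n_both_sites,
    n_forward_3p_match, n_strict_amplifiable, and the matching fractions
    (NaN for empty groups).  ``mismatch_histograms`` maps
    ``(group, primer_name)`` to a Counter of per-entry best mismatch counts.
    """

    table: pd.DataFrame
    mismatch_histograms: dict[tuple[str, str], Counter]


def coverage_table(
    refs,
    fwd_sites: Iterable[BindingSite],
    rev_sites: Iterable[BindingSite],
    hits: Iterable[AmpliconHit],
    fwd_name: str = "forward",
    rev_name: str = "reverse",
) -> CoverageTable:
    """Summarize binding-site and amplification coverage per taxon group.

    ``hits`` may come from a permissive policy; strict amplifiability is
    re-derived from the site flags (an entry is strictly amplifiable when
    some hit has 3'-compatible bases on both primers).
    """
    group_of = refs.group_of()
    groups = [g or "ungrouped" for g in group_of.values()]

    fwd_by_acc: dict[str, list[BindingSite]] = defaultdict(list)
    for s in fwd_sites:
        fwd_by_acc[s.accession].append(s)
    rev_by_acc: dict[str, list[BindingSite]] = defaultdict(list)
    for s in rev_sites:
        rev_by_acc[s.accession].append(s)

    strict_accs = {
        h.accession
        for h in hits
        if h.fwd_site.three_prime_match and h.rev_site.three_prime_match
    }

    tallies: dict[str, dict[str, int]] = {}
    hists: dict[tuple[str, str], Counter] = {}
    for entry in refs:
        acc = entry.accession
        label = group_of[acc] or "ungrouped"
        t = tallies.setdefault(
            label,
            {"n_total": 0, "n_both_sites": 0, "n_forward_3p_match": 0, "n_strict_amplifiable": 0},
        )
        t["n_total"] += 1
        has_fwd = bool(fwd_by_acc.get(acc))
        has_rev = bool(rev_by_acc.get(acc))
        if has_fwd and has_rev:
            t["n_both_sites"] += 1
        if any(s.three_prime_match for s in fwd_by_acc.get(acc, ())):
            t["n_forward_3p_match"] += 1
        if acc in strict_accs:
            t["n_strict_amplifiable"] += 1
        if has_fwd:
            hists.setdefault((label, fwd_name), Counter())[
                min(s.mismatches for s in fwd_by_acc[acc])
            ] += 1
        if has_rev:
            hists.setdefault((label, rev_name), Counter())[
                min(s.mismatches for s in rev_by_acc[acc])
            ] += 1

    order = list(dict.fromkeys(groups))
    rows = []
    for label in order:
        t = tallies.get(
            label,
            {"n_total": 0, "n_both_sites": 0, "n_forward_3p_match": 0, "n_strict_amplifiable": 0},
        )
        n = t["n_total"]
        rows.append(
            {
                "group": label,
                **t,
                "frac_both_sites": t["n_both_sites"] / n if n else np.nan,
                "frac_forward_3p_match": t["n_forward_3p_match"] / n if n else np.nan,
                "frac_strict_amplifiable": t["n_strict_amplifiable"] / n if n else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("group")
    return CoverageTable(table=table, mismatch_histograms=hists)


@dataclasses.dataclass(frozen=True)
class ResolutionScore:
    """Fraction of species (or amplicons) unambiguously identifiable."""

    rank: str
    value: float
    n_species: int
    n_amplicons: int
    mode: str


def resolution_score(
    hits: Iterable[AmpliconHit],
    species_of: Mapping[str, str],
    mode: str = "species-unique",
) -> ResolutionScore:
    """Taxonomic resolution of the amplicons at species rank.

    species-unique
        A species is *resolved* iff none of its distinct insert sequences is
        also produced by another species; value = resolved / species with a
        hit.  This is the default because "species resolution" is
        species-denominated.
    amplicon-lca
        value = distinct inserts produced by exactly one species / distinct
        inserts.
    """
    inserts_by_species: dict[str, set[str]] = defaultdict(set)
    species_by_insert: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        sp = species_of[h.accession]
        inserts_by_species[sp].add(h.insert)
        species_by_insert[h.insert].add(sp)
    if not inserts_by_species:
        raise ValueError("resolution_score needs at least one hit")
    n_species = len(inserts_by_species)
    n_amplicons = len(species_by_insert)
    if mode == "species-unique":
        resolved = sum(
            1
            for sp, inserts in inserts_by_species.items()
            if all(species_by_insert[ins] == {sp} for ins in inserts)
        )
        value = resolved / n_species
    elif mode == "amplicon-lca":
        unique = sum(1 for owners in species_by_insert.values() if len(owners) == 1)
        value = unique / n_amplicons
    else:
        raise ValueError(f"unknown resolution mode {mode!r}")
    return ResolutionScore(
        rank="species", value=value, n_species=n_species, n_amplicons=n_amplicons, mode=mode
    )


def shared_species_subset(
    hits_a: Iterable[AmpliconHit],
    hits_b: Iterable[AmpliconHit],
    species_of: Mapping[str, str],
) -> tuple[list[AmpliconHit], list[AmpliconHit]]:
    """Restrict two hit lists to the species present in both.

    Makes resolution scores comparable between primer sets with different
    taxonomic coverage.
    """
    hits_a = list(hits_a)
    hits_b = list(hits_b)
    species_a = {species_of[h.accession] for h in hits_a}
    species_b = {species_of[h.accession] for h in hits_b}
    shared = species_a & species_b
    return (
        [h for h in hits_a if species_of[h.accession] in shared],
        [h for h in hits_b if species_of[h.accession] in shared],
    )


def amplicon_stats(
    hits: Iterable[AmpliconHit], group_of: Mapping[str, str | None]
) -> pd.DataFrame:
    """Mean/SD of product length, insert length and insert GC per group.

    SD is the sample standard deviation (n-1); NaN for single-hit groups.
    """
    rows = [
        {
            "group": group_of.get(h.accession) or "ungrouped",
            "length": h.length,
            "insert_length": len(h.insert),
            "gc": h.gc,
        }
        for h in hits
    ]
    if not rows:
        raise ValueError("amplicon_stats needs at least one hit")
    df = pd.DataFrame(rows)
    out = df.groupby("group").agg(
        n=("length", "size"),
        length_mean=("length", "mean"),
        length_sd=("length", lambda s: s.std(ddof=1)),
        insert_length_mean=("insert_length", "mean"),
        insert_length_sd=("insert_length", lambda s: s.std(ddof=1)),
        gc_mean=("gc", "mean"),
        gc_sd=("gc", lambda s: s.std(ddof=1)),
    )
    return out


def plot_logo(pcm: PositionCountMatrix, ax=None):
    """Stacked-bar frequency logo for one position count matrix.

    Bars are per-position base frequencies (A green, C blue, G orange,
    T red, other grey); returns the matplotlib Axes.
    """
    import matplotlib

    if matplotlib.get_backend().lower() not in ("agg", "module://matplotlib_inline.backend_inline"):
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.4 * pcm.counts.shape[1] + 1, 2.5))
    freqs = pcm.frequencies()
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728", "other": "#7f7f7f"}
    bottom = np.zeros(freqs.shape[1])
    for base in PCM_ROWS:
        vals = freqs.loc[base].to_numpy(dtype=float)
        ax.bar(freqs.columns, vals, bottom=bottom, color=colors[base], label=base, width=0.8)
        bottom += vals
    ax.set_xlabel("primer position (5'->3')")
    ax.set_ylabel("frequency")
    ax.set_title(f"{pcm.primer_name} — {pcm.group} (n={pcm.n_sequences})")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7, ncol=5, loc="upper right")
    return ax
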