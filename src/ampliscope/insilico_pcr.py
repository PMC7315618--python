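"""In-silico PCR: degenerate primer matching with a strict 3'-terminal criterion.

The engine scans both strands of every template for windows matching each
primer under a mismatch budget (default 5 per primer), records per-site
diagnostics — mismatch count and whether the primer's 3'-terminal base is
compatible with the template — and pairs convergent forward/reverse sites
into predicted amplicons.  Under the default strict policy a site whose 3'
base mismatches the template is treated as non-extensible by the
polymerase, so it can never anchor a product; such sites are still
reported (flagged) because the 3' position is the most informative column
of a primer-coverage logo.

Coordinates are 0-based half-open on the forward strand.  ``site_seq`` is
the template sequence in *primer orientation* (reverse-complemented for
minus-strand sites) so logo columns line up with primer positions 5'->3'.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import MASK, clean_sequence, gc_fraction, iupac_compatible, reverse_complement
from .reference_io import ReferenceEntry, ReferenceSet

__all__ = [
    "Primer",
    "PrimerPair",
    "MatchPolicy",
    "BindingSite",
    "AmpliconHit",
    "MOZZIE_D2_UNI_F",
    "MOZZIE_D2_UNI_R",
    "DEFAULT_PRIMER_PAIR",
    "iupac_compatible",
    "score_site",
    "find_binding_sites",
    "scan_sequence",
    "amplify",
    "hits_to_dataframe",
    "sites_to_dataframe",
    "write_amplicons_fasta",
]

MIN_PRIMER_LENGTH = 8


@dataclasses.dataclass(frozen=True)
class Primer:
    """A PCR oligo, written 5'->3' on its own strand."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", clean_sequence(self.seq, context=f"primer {self.name!r}"))
        if len(self.seq) < MIN_PRIMER_LENGTH:
            raise ValueError(
                f"primer {self.name!r} is {len(self.seq)} nt; minimum is {MIN_PRIMER_LENGTH}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer

    def __post_init__(self) -> None:
        if self.forward.name == self.reverse.name:
            raise ValueError("forward and reverse primers must have distinct names")


# The universal-mosquito D2 (28S expansion segment) pair used as defaults.
# The forward primer ends in C; that 3'-cytosine is the clade-diagnostic
# base that excludes most non-culicid templates under the strict policy.
MOZZIE_D2_UNI_F = Primer("Mozzie.D2.Uni.F", "AAGCACTCTGAATAGAGAGTC")
MOZZIE_D2_UNI_R = Primer("Mozzie.D2.Uni.R", "TGGTCCGTGTTTCAAGAC")
DEFAULT_PRIMER_PAIR = PrimerPair(MOZZIE_D2_UNI_F, MOZZIE_D2_UNI_R)


@dataclasses.dataclass(frozen=True)
class MatchPolicy:
    """Amplification acceptance rules.

    max_mismatches
        Per-primer mismatch budget over the whole oligo (3' mismatches count
        here too: one event, two consequences).
    require_three_prime
        When true, a product requires both primers' 3'-terminal window to be
        compatible with the template (no polymerase extension otherwise).
    max_amplicon_length
        Primer-inclusive cap on product length.
    three_prime_window
        Number of 3'-terminal bases that must all match for the 3' criterion
        (default 1: exactly the terminal nucleotide).
    """

    max_mismatches: int = 5
    require_three_prime: bool = True
    max_amplicon_length: int = 2000
    three_prime_window: int = 1

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.three_prime_window < 1:
            raise ValueError("three_prime_window must be >= 1")
        if self.max_amplicon_length < 2 * MIN_PRIMER_LENGTH:
            raise ValueError("max_amplicon_length must exceed combined primer length")


@dataclasses.dataclass(frozen=True)
class BindingSite:
    """One primer/template alignment window.

    ``start``/``end`` are 0-based half-open on the forward strand regardless
    of ``strand``; ``site_seq`` is the template in primer orientation.
    """

    accession: str
    strand: str  # "+" or "-"
    start: int
    end: int
    mismatches: int
    three_prime_match: bool
    site_seq: str


@dataclasses.dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product in forward-primer orientation."""

    accession: str
    fwd_site: BindingSite
    rev_site: BindingSite
    product: str
    insert: str
    length: int
    gc: float


def score_site(primer: Primer, window: str, three_prime_window: int = 1) -> tuple[int, bool]:
    """Score a primer against an equal-length template window.

    Returns ``(mismatches, three_prime_match)`` where mismatches counts
    positions whose IUPAC sets are disjoint (the 3' position included) and
    ``three_prime_match`` is True iff the last ``three_prime_window`` primer
    bases are all compatible with the template.
    """
    if len(window) != len(primer):
        raise ValueError(
            f"window length {len(window)} != primer length {len(primer)}"
        )
    mismatches = sum(
        1 for p, t in zip(primer.seq, window) if not MASK[p] & MASK[t]
    )
    tail = slice(len(primer) - three_prime_window, len(primer))
    three_prime = all(
        MASK[p] & MASK[t] for p, t in zip(primer.seq[tail], window[tail])
    )
    return mismatches, three_prime


def scan_sequence(
    primer: Primer, seq: str, policy: MatchPolicy, accession: str = "seq"
) -> list[BindingSite]:
    """All binding sites of ``primer`` on both strands of ``seq``.

    Sites within the mismatch budget are returned even when their 3' base
    mismatches (``three_prime_match=False``); exclusion under the strict
    policy happens when pairing sites in :func:`amplify`.
    """
    m = len(primer)
    n = len(seq)
    if n < m:
        return []
    budget = policy.max_mismatches
    k = policy.three_prime_window
    pmask = [MASK[c] for c in primer.seq]
    rc_primer = reverse_complement(primer.seq)
    rmask = [MASK[c] for c in rc_primer]
    smask = [MASK[c] for c in seq]
    sites: list[BindingSite] = []
    for i in range(n - m + 1):
        # plus strand: primer 3' end at window right edge
        mm = 0
        for j in range(m):
            if not pmask[j] & smask[i + j]:
                mm += 1
                if mm > budget:
                    break
        if mm <= budget:
            three = all(pmask[j] & smask[i + j] for j in range(m - k, m))
            sites.append(
                BindingSite(
                    accession=accession,
                    strand="+",
                    start=i,
                    end=i + m,
                    mismatches=mm,
                    three_prime_match=three,
                    site_seq=seq[i : i + m],
                )
            )
        # minus strand: compare reverse-complemented primer to the window;
        # the primer's 3' base sits at the window's left edge.
        mm = 0
        for j in range(m):
            if not rmask[j] & smask[i + j]:
                mm += 1
                if mm > budget:
                    break
        if mm <= budget:
            three = all(rmask[j] & smask[i + j] for j in range(k))
            sites.append(
                BindingSite(
                    accession=accession,
                    strand="-",
                    start=i,
                    end=i + m,
                    mismatches=mm,
                    three_prime_match=three,
                    site_seq=reverse_complement(seq[i : i + m]),
                )
            )
    return sites


def find_binding_sites(
    primer: Primer, entry: ReferenceEntry, policy: MatchPolicy
) -> list[BindingSite]:
    """Binding sites of ``primer`` in a reference entry (both strands)."""
    return scan_sequence(primer, entry.seq, policy, accession=entry.accession)


def _pair_sites(
    seq: str,
    accession: str,
    fwd_sites: list[BindingSite],
    rev_sites: list[BindingSite],
    policy: MatchPolicy,
    fwd_len: int,
    rev_len: int,
) -> list[AmpliconHit]:
    hits: list[AmpliconHit] = []
    strict = policy.require_three_prime
    max_len = policy.max_amplicon_length
    for f in fwd_sites:
        if strict and not f.three_prime_match:
            continue
        for r in rev_sites:
            if strict and not r.three_prime_match:
                continue
            if f.strand == "+" and r.strand == "-" and r.start >= f.end:
                length = r.end - f.start
                if length > max_len:
                    continue
                product = seq[f.start : r.end]
            elif f.strand == "-" and r.strand == "+" and f.start >= r.end:
                length = f.end - r.start
                if length > max_len:
                    continue
                product = reverse_complement(seq[r.start : f.end])
            else:
                continue
            insert = product[fwd_len : length - rev_len]
            hits.append(
                AmpliconHit(
                    accession=accession,
                    fwd_site=f,
                    rev_site=r,
                    product=product,
                    insert=insert,
                    length=length,
                    gc=gc_fraction(insert),
                )
            )
    return hits


def amplify(
    pair: PrimerPair, refs: ReferenceSet | Iterable[ReferenceEntry], policy: MatchPolicy
) -> list[AmpliconHit]:
    """Predict PCR products for every reference entry.

    Every convergent (forward site, reverse site on the opposite strand)
    combination within ``max_amplicon_length`` yields a hit — no
    shortest-product collapsing; downstream metrics deduplicate per
    accession where needed.  Under ``require_three_prime`` both sites must
    carry a compatible 3'-terminal base.
    """
    hits: list[AmpliconHit] = []
    for entry in refs:
        fwd_sites = scan_sequence(pair.forward, entry.seq, policy, entry.accession)
        rev_sites = scan_sequence(pair.reverse, entry.seq, policy, entry.accession)
        hits.extend(
            _pair_sites(
                entry.seq,
                entry.accession,
                fwd_sites,
                rev_sites,
                policy,
                len(pair.forward),
                len(pair.reverse),
            )
        )
    return hits


def sites_to_dataframe(sites: Iterable[BindingSite], primer_name: str) -> pd.DataFrame:
    rows = [
        {
            "accession": s.accession,
            "primer": primer_name,
            "strand": s.strand,
            "start": s.start,
            "end": s.end,
            "mismatches": s.mismatches,
            "three_prime_match": s.three_prime_match,
            "site_seq": s.site_seq,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "primer", "strand", "start", "end",
            "mismatches", "three_prime_match", "site_seq",
        ],
    )


def hits_to_dataframe(
    hits: Iterable[AmpliconHit],
    species_of: dict[str, str] | None = None,
    group_of: dict[str, str | None] | None = None,
) -> pd.DataFrame:
    """Tabulate hits with the per-site diagnostics (one row per product)."""
    rows = []
    for h in hits:
        rows.append(
            {
                "accession": h.accession,
                "species": (species_of or {}).get(h.accession, ""),
                "group": (group_of or {}).get(h.accession, "") or "",
                "strand": h.fwd_site.strand,
                "fwd_start": h.fwd_site.start,
                "fwd_mm": h.fwd_site.mismatches,
                "fwd_3p": h.fwd_site.three_prime_match,
                "rev_start": h.rev_site.start,
                "rev_mm": h.rev_site.mismatches,
                "rev_3p": h.rev_site.three_prime_match,
                "length": h.length,
                "gc": round(h.gc, 6),
                "insert": h.insert,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "species", "group", "strand", "fwd_start", "fwd_mm",
            "fwd_3p", "rev_start", "rev_mm", "rev_3p", "length", "gc", "insert",
        ],
    )


def write_amplicons_fasta(hits: Iterable[AmpliconHit], path) -> None:
    """Write predicted products (forward-primer orientation) as FASTA."""
    records = []
    for i, h in enumerate(hits):
        records.append(
            SeqRecord(
                Seq(h.product),
                id=f"{h.accession}|amplicon{i}",
                description=f"start={h.fwd_site.start} length={h.length}",
            )
        )
    SeqIO.write(records, str(path), "fasta")
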