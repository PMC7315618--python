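"""Read, validate, group and filter taxonomically annotated reference sequences.

A reference set pairs each FASTA record with a row from a flat taxonomy
table (TSV with at least ``accession``, ``species`` columns plus rank
columns such as ``order``, ``suborder``, ``family``).  Grouping schemes
partition a set into the ordered taxon bins used for coverage reporting —
by default the bins used for mosquito-trap bycatch evaluation: Culicidae,
non-culicid Nematocera, Hymenoptera, Lepidoptera, Coleoptera, and a
catch-all for all remaining arthropods.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from collections.abc import Callable, Iterable, Iterator, Mapping, Sequence
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import SequenceAlphabetError, clean_sequence

__all__ = [
    "TaxonRecord",
    "ReferenceEntry",
    "ReferenceSet",
    "GroupingScheme",
    "default_grouping_scheme",
    "load_reference_set",
    "write_reference_set",
    "assign_groups",
    "group_counts",
    "filter_by_flank",
]


@dataclasses.dataclass(frozen=True)
class TaxonRecord:
    """Taxonomic annotation for one reference sequence."""

    accession: str
    species: str
    lineage: Mapping[str, str] = dataclasses.field(default_factory=dict)
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.species:
            raise ValueError(f"species missing for accession {self.accession!r}")
        object.__setattr__(self, "lineage", dict(self.lineage))

    def rank(self, name: str) -> str | None:
        return self.lineage.get(name)

    def with_group(self, label: str) -> "TaxonRecord":
        return dataclasses.replace(self, group=label)


@dataclasses.dataclass(frozen=True)
class ReferenceEntry:
    """One annotated reference sequence."""

    taxon: TaxonRecord
    seq: str

    @property
    def accession(self) -> str:
        return self.taxon.accession

    def __len__(self) -> int:
        return len(self.seq)


class ReferenceSet:
    """Ordered collection of :class:`ReferenceEntry` with unique accessions.

    Iteration order is input order; lookup by accession is O(1).
    """

    def __init__(self, entries: Iterable[ReferenceEntry]):
        self._entries: list[ReferenceEntry] = list(entries)
        self._index: dict[str, ReferenceEntry] = {}
        for entry in self._entries:
            acc = entry.accession
            if acc in self._index:
                raise ValueError(f"duplicate accession {acc!r} in reference set")
            self._index[acc] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[ReferenceEntry]:
        return iter(self._entries)

    def __getitem__(self, accession: str) -> ReferenceEntry:
        return self._index[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._index

    @property
    def accessions(self) -> list[str]:
        return [e.accession for e in self._entries]

    def species_of(self) -> dict[str, str]:
        """Accession -> species mapping."""
        return {e.accession: e.taxon.species for e in self._entries}

    def group_of(self) -> dict[str, str | None]:
        """Accession -> group-label mapping (labels may be None before grouping)."""
        return {e.accession: e.taxon.group for e in self._entries}


Predicate = Callable[[TaxonRecord], bool]


class GroupingScheme:
    """Ordered list of ``(label, predicate)`` bins; the first matching bin wins.

    The final bin must be a catch-all (predicate true for every record) so
    that the labels partition any input set.
    """

    def __init__(self, bins: Sequence[tuple[str, Predicate]]):
        if not bins:
            raise ValueError("grouping scheme needs at least one bin")
        self.bins = list(bins)

    @classmethod
    def from_rank_rules(
        cls,
        rules: Sequence[tuple[str, Mapping[str, str]]],
        catch_all: str = "all other arthropods",
    ) -> "GroupingScheme":
        """Build a scheme from rank-equality rules, appending a catch-all bin.

        Each rule is ``(label, {rank: required_name, ...})``; a record matches
        when every listed rank carries the required name.
        """

        def make_pred(required: Mapping[str, str]) -> Predicate:
            items = tuple(required.items())

            def pred(taxon: TaxonRecord) -> bool:
                return all(taxon.rank(rank) == name for rank, name in items)

            return pred

        bins = [(label, make_pred(req)) for label, req in rules]
        bins.append((catch_all, lambda taxon: True))
        return cls(bins)

    def label_for(self, taxon: TaxonRecord) -> str:
        for label, pred in self.bins:
            if pred(taxon):
                return label
        raise ValueError(
            f"no bin matched accession {taxon.accession!r}; scheme lacks a catch-all"
        )


def default_grouping_scheme() -> GroupingScheme:
    """The standard trap-bycatch bins for mosquito primer evaluation.

    Culicidae first (so culicid Nematocera never fall into the Nematocera
    bin), then non-culicid Nematocera, the three holometabolan bycatch
    orders, and a catch-all for every remaining arthropod.
    """
    return GroupingScheme.from_rank_rules(
        [
            ("Culicidae", {"family": "Culicidae"}),
            ("non-culicid Nematocera", {"suborder": "Nematocera"}),
            ("Hymenoptera", {"order": "Hymenoptera"}),
            ("Lepidoptera", {"order": "Lepidoptera"}),
            ("Coleoptera", {"order": "Coleoptera"}),
        ]
    )


_RESERVED_COLUMNS = ("accession", "species")


def _lineage_from_row(row: pd.Series) -> dict[str, str]:
    lineage = {}
    for rank, value in row.items():
        if rank in _RESERVED_COLUMNS:
            continue
        if isinstance(value, str) and value.strip():
            lineage[str(rank)] = value.strip()
    return lineage


def load_taxonomy_table(taxonomy_path: str | Path) -> dict[str, TaxonRecord]:
    """Parse a taxonomy TSV into accession-keyed :class:`TaxonRecord` objects."""
    table = pd.read_csv(taxonomy_path, sep="\t", dtype=str).fillna("")
    for col in _RESERVED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"taxonomy table lacks required column {col!r}")
    records: dict[str, TaxonRecord] = {}
    for _, row in table.iterrows():
        acc = row["accession"].strip()
        if acc in records:
            raise ValueError(f"duplicate accession {acc!r} in taxonomy table")
        records[acc] = TaxonRecord(
            accession=acc, species=row["species"].strip(), lineage=_lineage_from_row(row)
        )
    return records


def load_reference_set(fasta_path: str | Path, taxonomy_path: str | Path) -> ReferenceSet:
    """Load FASTA + taxonomy TSV into a validated :class:`ReferenceSet`.

    The FASTA id is the token before the first whitespace.  Every id must
    resolve in the taxonomy table (error names the accession otherwise) and
    every residue must be an IUPAC DNA code (error gives the position);
    lowercase input is uppercased silently.
    """
    taxonomy = load_taxonomy_table(taxonomy_path)
    entries = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        acc = record.id
        if acc in seen:
            raise ValueError(f"duplicate FASTA id {acc!r}")
        seen.add(acc)
        if acc not in taxonomy:
            raise KeyError(f"accession {acc!r} missing from taxonomy table")
        try:
            seq = clean_sequence(str(record.seq), context=f"record {acc!r}")
        except SequenceAlphabetError:
            raise
        entries.append(ReferenceEntry(taxon=taxonomy[acc], seq=seq))
    return ReferenceSet(entries)


def write_reference_set(
    refs: ReferenceSet, fasta_path: str | Path, taxonomy_path: str | Path
) -> None:
    """Write a reference set back to FASTA + taxonomy TSV (round-trip safe)."""
    records = [
        SeqRecord(Seq(e.seq), id=e.accession, description="") for e in refs
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    ranks: list[str] = []
    for entry in refs:
        for rank in entry.taxon.lineage:
            if rank not in ranks:
                ranks.append(rank)
    rows = []
    for entry in refs:
        row = {"accession": entry.accession, "species": entry.taxon.species}
        for rank in ranks:
            row[rank] = entry.taxon.lineage.get(rank, "")
        rows.append(row)
    pd.DataFrame(rows, columns=["accession", "species", *ranks]).to_csv(
        taxonomy_path, sep="\t", index=False
    )


def assign_groups(refs: ReferenceSet, scheme: GroupingScheme) -> ReferenceSet:
    """Label every entry with its first matching bin; returns a new set."""
    return ReferenceSet(
        ReferenceEntry(taxon=e.taxon.with_group(scheme.label_for(e.taxon)), seq=e.seq)
        for e in refs
    )


def group_counts(refs: ReferenceSet) -> Counter:
    """Entries per group label (labels partition the set once assigned)."""
    return Counter(e.taxon.group for e in refs)


def filter_by_flank(
    refs: ReferenceSet,
    sites_by_accession: Mapping[str, Sequence],
    min_flank: int = 30,
) -> ReferenceSet:
    """Keep entries with >=1 binding site flanked by ``min_flank`` residues on both sides.

    A site with forward-strand coordinates ``[start, end)`` in an entry of
    length L qualifies when ``start >= min_flank`` and
    ``L - end >= min_flank``.  This drops database records that are likely
    primer-inclusive amplicon submissions rather than genomic context.
    """
    kept = []
    for entry in refs:
        sites = sites_by_accession.get(entry.accession, ())
        for site in sites:
            if site.start >= min_flank and len(entry.seq) - site.end >= min_flank:
                kept.append(entry)
                break
    return ReferenceSet(kept)
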