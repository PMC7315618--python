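"""Per-specimen variant libraries and exact-identity read assignment.

Mirrors the reference-library workflow for pooled amplicon runs: each
specimen is sequenced individually, minor variants below 1% of its reads
are discarded as probable cross-specimen contamination, the surviving
variants form a species-labelled library, and pooled reads are assigned
only on 100% identity to a library variant (anything else is unassigned).
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from collections.abc import Iterable, Mapping
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import clean_sequence

__all__ = [
    "VariantRecord",
    "ReferenceLibrary",
    "AssignmentResult",
    "filter_minor_variants",
    "build_library",
    "assign_reads",
]


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One library variant with its provenance."""

    species: str
    specimen: str
    seq: str
    frequency: float  # within-individual frequency


class ReferenceLibrary:
    """Species -> variant sequences, with a uniqueness guarantee.

    No variant sequence may appear under two species; this is enforced at
    construction because a shared sequence signals contamination (or a
    mock-data defect) and would make exact-identity assignment ambiguous.
    """

    def __init__(self, variants: Iterable[VariantRecord]):
        self.variants: list[VariantRecord] = list(variants)
        self._species_of: dict[str, str] = {}
        for v in self.variants:
            prev = self._species_of.get(v.seq)
            if prev is not None and prev != v.species:
                raise ValueError(
                    f"variant shared between species {prev!r} and {v.species!r}: "
                    f"{v.seq[:40]}..."
                )
            self._species_of[v.seq] = v.species

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def species(self) -> list[str]:
        return sorted({v.species for v in self.variants})

    def variants_of(self, species: str) -> list[VariantRecord]:
        return [v for v in self.variants if v.species == species]

    def lookup(self, seq: str) -> str | None:
        """Species owning ``seq``, or None (exact identity only)."""
        return self._species_of.get(seq)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(
                Seq(v.seq),
                id=f"{v.species}|{v.specimen}|{v.frequency:.6f}".replace(" ", "_"),
                description="",
            )
            for v in self.variants
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceLibrary":
        variants = []
        for record in SeqIO.parse(str(path), "fasta"):
            species, specimen, freq = record.id.split("|")
            variants.append(
                VariantRecord(
                    species=species.replace("_", " "),
                    specimen=specimen,
                    seq=clean_sequence(str(record.seq), context=f"variant {record.id!r}"),
                    frequency=float(freq),
                )
            )
        return cls(variants)


@dataclasses.dataclass
class AssignmentResult:
    """Per-read labels and per-species tallies for one pool."""

    labels: list[str]  # species or "unassigned", aligned with the input reads
    counts: Counter  # species -> assigned read count
    unassigned: int

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unassigned


def filter_minor_variants(
    variant_counts: Mapping[str, int], threshold: float = 0.01
) -> dict[str, int]:
    """Drop variants carrying *fewer than* ``threshold`` of the total reads.

    A variant at exactly the threshold is kept (the removal rule is
    strictly-fewer-than).  All-zero input is an error.
    """
    total = sum(variant_counts.values())
    if total <= 0:
        raise ValueError("variant counts sum to zero; nothing to filter")
    return {
        seq: count
        for seq, count in variant_counts.items()
        if count / total >= threshold
    }


def build_library(
    per_specimen_variants: Mapping[str, tuple[str, Mapping[str, float]]],
) -> ReferenceLibrary:
    """Assemble a library from per-specimen variant tables.

    ``per_specimen_variants`` maps specimen id -> (species,
    {variant sequence -> weight}); weights (read counts or frequencies) are
    normalized per specimen.  Variants are expected to be pre-filtered
    (see :func:`filter_minor_variants`).  A sequence appearing under two
    species raises an error naming both.
    """
    owners: dict[str, str] = {}
    variants: list[VariantRecord] = []
    for specimen, (species, table) in per_specimen_variants.items():
        total = sum(table.values())
        if total <= 0:
            raise ValueError(f"specimen {specimen!r} has no variant mass")
        for seq, weight in table.items():
            seq = clean_sequence(seq, context=f"specimen {specimen!r} variant")
            prev = owners.get(seq)
            if prev is not None and prev != species:
                raise ValueError(
                    f"variant shared between species {prev!r} and {species!r} "
                    f"(specimen {specimen!r})"
                )
            owners[seq] = species
            variants.append(
                VariantRecord(
                    species=species,
                    specimen=specimen,
                    seq=seq,
                    frequency=weight / total,
                )
            )
    return ReferenceLibrary(variants)


def assign_reads(reads: Iterable[str], lib: ReferenceLibrary) -> AssignmentResult:
    """Assign each read by exact identity to a library variant.

    A read is assigned iff it is character-identical (after uppercase
    normalization) to some variant; species counts sum reads across that
    species' variants.  Everything else is unassigned.
    """
    labels: list[str] = []
    counts: Counter = Counter()
    unassigned = 0
    for read in reads:
        species = lib.lookup(read.upper())
        if species is None:
            labels.append("unassigned")
            unassigned += 1
        else:
            labels.append(species)
            counts[species] += 1
    return AssignmentResult(labels=labels, counts=counts, unassigned=unassigned)
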