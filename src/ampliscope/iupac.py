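"""IUPAC nucleotide alphabet: validation, complementation and degenerate matching.

All sequence data in the package (primers, templates, amplicons, reads) is
held as plain uppercase ``str`` over the 15-letter IUPAC DNA alphabet,
validated on entry by :func:`clean_sequence`.  Degenerate codes denote sets
of bases (``R`` = A/G, ``N`` = any, ...); two codes are *compatible* when
their base sets intersect, which is the matching rule used throughout the
in-silico PCR engine.
"""

from __future__ import annotations

__all__ = [
    "IUPAC_SETS",
    "IUPAC_CODES",
    "clean_sequence",
    "reverse_complement",
    "iupac_compatible",
    "gc_fraction",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_CODES: frozenset[str] = frozenset(IUPAC_SETS)

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(_COMPLEMENT)

# Bitmask per code (A=1, C=2, G=4, T=8); codes are compatible iff the masks
# share a bit.  Used in the inner scanning loops.
MASK: dict[str, int] = {
    code: sum({"A": 1, "C": 2, "G": 4, "T": 8}[b] for b in bases)
    for code, bases in IUPAC_SETS.items()
}


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains a character outside the IUPAC DNA alphabet."""


def clean_sequence(raw: str, *, context: str = "sequence") -> str:
    """Uppercase-normalize ``raw`` and validate it against the IUPAC DNA alphabet.

    ``U`` is rejected (DNA only), as is any non-IUPAC character; the error
    message names the offending character and its 0-based position.  Empty
    input is an error.
    """
    if not raw:
        raise SequenceAlphabetError(f"{context} is empty")
    seq = raw.upper()
    for pos, char in enumerate(seq):
        if char not in IUPAC_CODES:
            raise SequenceAlphabetError(
                f"{context} contains illegal residue {char!r} at position {pos}"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (degenerate codes map to their complements)."""
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def iupac_compatible(pattern_base: str, template_base: str) -> bool:
    """True iff the base sets of two IUPAC codes intersect.

    This is the degenerate-aware match test used for primer/template
    comparison: ``R`` matches ``G`` (sets {A,G} and {G} intersect), ``C``
    does not match ``T``, and ``N`` matches everything.
    """
    try:
        return bool(MASK[pattern_base] & MASK[template_base])
    except KeyError as exc:
        raise SequenceAlphabetError(f"not an IUPAC code: {exc.args[0]!r}") from None


def gc_fraction(seq: str) -> float:
    """Fraction of residues that are unambiguously G or C (``G``, ``C`` or ``S``).

    Other ambiguity codes do not count toward GC; the empty string yields 0.
    """
    if not seq:
        return 0.0
    gc = sum(1 for c in seq if c in "GCS")
    return gc / len(seq)
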