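import pytest

from ampliscope import (
    AmpliconHit,
    BindingSite,
    MatchPolicy,
    SyntheticRefConfig,
    amplify,
    assign_groups,
    default_grouping_scheme,
    DEFAULT_PRIMER_PAIR,
    synth_reference_set,
)
from ampliscope.iupac import gc_fraction


TINY_FASTA = """\
>acc1 some description
ACGTACGTACGTACGTACGT
>acc2
ttttACGTACGTacgt
>acc3
GGGGCCCCAAAATTTT
"""

TINY_TAX = """\
accession\tspecies\torder\tsuborder\tfamily
acc1\tCulex synthetic\tDiptera\tNematocera\tCulicidae
acc2\tChironomus synthetic\tDiptera\tNematocera\tChironomidae
acc3\tLycosa synthetic\tAraneae\tAraneomorphae\tLycosidae
"""


@pytest.fixture
def tiny_ref_files(tmp_path):
    fasta = tmp_path / "refs.fa"
    tax = tmp_path / "tax.tsv"
    fasta.write_text(TINY_FASTA)
    tax.write_text(TINY_TAX)
    return fasta, tax


@pytest.fixture(scope="session")
def planted():
    """Default synthetic reference set, grouped, with its variant library."""
    refs, library = synth_reference_set(SyntheticRefConfig(seed=42))
    refs = assign_groups(refs, default_grouping_scheme())
    return refs, library


@pytest.fixture(scope="session")
def planted_hits(planted):
    refs, _ = planted
    strict = amplify(DEFAULT_PRIMER_PAIR, refs, MatchPolicy())
    relaxed = amplify(DEFAULT_PRIMER_PAIR, refs, MatchPolicy(require_three_prime=False))
    return strict, relaxed


def make_hit(
    accession: str,
    insert: str,
    fwd_len: int = 10,
    rev_len: int = 10,
    fwd_3p: bool = True,
    rev_3p: bool = True,
    mismatches: int = 0,
) -> AmpliconHit:
    """Fabricate a minimal AmpliconHit for metric-level tests."""
    length = fwd_len + len(insert) + rev_len
    fwd = BindingSite(
        accession=accession, strand="+", start=0, end=fwd_len,
        mismatches=mismatches, three_prime_match=fwd_3p, site_seq="A" * fwd_len,
    )
    rev = BindingSite(
        accession=accession, strand="-", start=length - rev_len, end=length,
        mismatches=mismatches, three_prime_match=rev_3p, site_seq="A" * rev_len,
    )
    product = "A" * fwd_len + insert + "A" * rev_len
    return AmpliconHit(
        accession=accession, fwd_site=fwd, rev_site=rev,
        product=product, insert=insert, length=length, gc=gc_fraction(insert),
    )
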