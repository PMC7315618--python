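"""Synthetic D2-like reference sets and pooled-read simulation.

Every downstream module is testable without database downloads because this
generator emulates the two data layers of a mosquito-metabarcoding study:

* a reference set in which the reverse priming site is conserved across all
  clades while the forward site's 3'-terminal base (a cytosine) is carried
  only by the target clade — so the strict 3'-anchor policy amplifies the
  target and excludes everything else by construction; target species carry
  unique variable inserts (with within-individual variants from SNPs and
  microsatellite-like indels), split into a short-insert clade
  (Culicinae-like, 383 +/- 9 nt) and a long-insert clade (Anophelinae-like,
  432 +/- 24 nt) at ~60% GC;

* pooled read counts drawn multinomially from per-species weights
  volume x amplifiability x degradation, with optional bycatch mass (one
  dominant family, emulating Chaoboridae), carryover contamination (target
  tissue inside the bycatch), and a quality-filter loss applied to the raw
  depth (default 20%).

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np

from .assignment import ReferenceLibrary, VariantRecord
from .insilico_pcr import MOZZIE_D2_UNI_F, MOZZIE_D2_UNI_R
from .iupac import reverse_complement
from .pool_quant import PoolDesign
from .reference_io import ReferenceEntry, ReferenceSet, TaxonRecord

__all__ = [
    "SyntheticRefConfig",
    "SpecimenModel",
    "PoolSimConfig",
    "SimulatedRun",
    "synth_reference_set",
    "true_proportions",
    "simulate_reads",
    "sample_read_sequences",
    "make_fresh_pool_design",
    "make_specimens",
    "simulate_fresh_pools",
    "OFFTARGET_LINEAGES",
]

_BASES = np.array(list("ACGT"))

# Lineages for the shipped off-target families (trap-bycatch flavored).
OFFTARGET_LINEAGES: dict[str, dict[str, str]] = {
    "Chironomidae": {"order": "Diptera", "suborder": "Nematocera", "family": "Chironomidae"},
    "Chaoboridae": {"order": "Diptera", "suborder": "Nematocera", "family": "Chaoboridae"},
    "Formicidae": {"order": "Hymenoptera", "suborder": "Apocrita", "family": "Formicidae"},
    "Noctuidae": {"order": "Lepidoptera", "suborder": "Glossata", "family": "Noctuidae"},
    "Carabidae": {"order": "Coleoptera", "suborder": "Adephaga", "family": "Carabidae"},
    "Lycosidae": {"order": "Araneae", "suborder": "Araneomorphae", "family": "Lycosidae"},
}


@dataclasses.dataclass(frozen=True)
class SyntheticRefConfig:
    """Parameters of the planted reference set.

    Defaults mirror the study conditions being emulated: 17 target species
    (3 of them in the long-insert anopheline-like clade), insert lengths
    383 +/- 9 and 432 +/- 24 nt, 60% GC, 1–6 within-individual variants per
    specimen.
    """

    n_target_species: int = 17
    n_clade_b: int = 3  # long-insert (anopheline-like) subset of the targets
    offtarget_groups: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {
            "Chironomidae": 4, "Chaoboridae": 3, "Formicidae": 4,
            "Noctuidae": 4, "Carabidae": 4, "Lycosidae": 3,
        }
    )
    insert_len_a: tuple[float, float] = (383.0, 9.0)  # mean, SD (nt)
    insert_len_b: tuple[float, float] = (432.0, 24.0)
    offtarget_insert_len: tuple[float, float] = (400.0, 30.0)
    gc: float = 0.60
    variants_min: int = 1
    variants_max: int = 6
    microsat_indel_prob: float = 0.4  # chance a variant mutation is an indel, not a SNP
    offtarget_extra_mismatches: int = 2  # max internal forward-site substitutions
    flank_len: int = 40  # >= the 30 nt flank-filter threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clade_b > self.n_target_species:
            raise ValueError("n_clade_b cannot exceed n_target_species")
        if not 1 <= self.variants_min <= self.variants_max:
            raise ValueError("need 1 <= variants_min <= variants_max")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0,1)")


@dataclasses.dataclass(frozen=True)
class SpecimenModel:
    """Amplification behaviour of one specimen's DNA stock."""

    species: str
    amplifiability: float = 1.0  # amplifiable-template units per µL
    degradation: float = 1.0  # multiplicative loss in (0, 1]

    def __post_init__(self) -> None:
        if self.amplifiability <= 0:
            raise ValueError("amplifiability must be > 0")
        if not 0 < self.degradation <= 1:
            raise ValueError("degradation must be in (0, 1]")


@dataclasses.dataclass(frozen=True)
class PoolSimConfig:
    """One simulated sequencing run of one pool.

    ``bycatch_dna_ratio`` r adds r x ``bycatch_unit_mass`` of non-target
    amplifiable mass per unit of (normalized) target mass, mirroring the
    1:1 / 1:10 mixing designs; ``carryover_fraction`` is the part of that
    bycatch mass that is really target-species tissue carryover, spread
    uniformly over ``contaminated_species`` (all design species when empty).
    """

    design: PoolDesign
    specimens: Sequence[SpecimenModel]
    depth: int
    bycatch_dna_ratio: float = 0.0
    carryover_fraction: float = 0.0
    bycatch_unit_mass: float = 1.0
    quality_loss: float = 0.20
    bycatch_family_weights: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"Chaoboridae": 0.7, "Chironomidae": 0.2, "Ceratopogonidae": 0.1}
    )
    contaminated_species: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.quality_loss < 1:
            raise ValueError("quality_loss must be in [0, 1)")
        if not 0 <= self.carryover_fraction <= 1:
            raise ValueError("carryover_fraction must be in [0, 1]")
        if self.bycatch_dna_ratio < 0:
            raise ValueError("bycatch_dna_ratio must be >= 0")
        missing = [s.species for s in self.specimens if s.species not in self.design.volumes]
        extra = set(self.design.volumes) - {s.species for s in self.specimens}
        if extra:
            raise ValueError(f"design species without specimen model: {sorted(extra)}")
        del missing  # specimens absent from the design simply contribute nothing


@dataclasses.dataclass
class SimulatedRun:
    """Read counts plus the ground truth that generated them."""

    pool_id: str
    read_table: dict[str, int]  # target species (carryover merged in)
    bycatch_counts: dict[str, int]  # bycatch family -> reads
    provenance: dict[str, int]  # {"target", "bycatch", "contaminant"} tallies
    true_proportions: dict[str, float]  # full category map (see true_proportions)
    depth_requested: int
    raw_depth: int
    realized_depth: int
    seed: int


def _random_insert(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _mutate_variant(rng: np.random.Generator, insert: str, indel_prob: float) -> str:
    """One mutational step: a SNP, or a microsatellite-like 2-nt slippage indel."""
    s = list(insert)
    if rng.random() < indel_prob and len(s) > 10:
        pos = int(rng.integers(1, len(s) - 2))
        if rng.random() < 0.5:
            s[pos:pos] = s[pos : pos + 2]  # duplicate a dinucleotide unit
        else:
            del s[pos : pos + 2]
    else:
        pos = int(rng.integers(0, len(s)))
        alternatives = [b for b in "ACGT" if b != s[pos]]
        s[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(s)


def synth_reference_set(cfg: SyntheticRefConfig) -> tuple[ReferenceSet, ReferenceLibrary]:
    """Generate the planted reference set and its per-specimen variant library.

    Target entries carry the exact forward priming site (3'-C included) and
    the conserved reverse site around a species-unique insert; off-target
    entries keep the reverse site but their forward site ends in T instead
    of C (plus up to ``offtarget_extra_mismatches`` internal substitutions).
    The library holds every within-individual variant *insert* (the
    primer-trimmed amplicon) with its frequency.  Deterministic under
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    fwd = MOZZIE_D2_UNI_F.seq
    rev_site_template = reverse_complement(MOZZIE_D2_UNI_R.seq)
    fwd_off = fwd[:-1] + "T"  # 3'-C -> T: non-extensible under the strict policy

    used_inserts: set[str] = set()

    def fresh_insert(mean: float, sd: float) -> str:
        while True:
            length = max(60, int(round(rng.normal(mean, sd))))
            ins = _random_insert(rng, length, cfg.gc)
            if ins not in used_inserts:
                used_inserts.add(ins)
                return ins

    entries: list[ReferenceEntry] = []
    variants: list[VariantRecord] = []
    acc_counter = 0

    def next_acc() -> str:
        nonlocal acc_counter
        acc_counter += 1
        return f"SYN{acc_counter:04d}"

    for i in range(cfg.n_target_species):
        clade_b = i < cfg.n_clade_b
        mean, sd = cfg.insert_len_b if clade_b else cfg.insert_len_a
        genus = "Anophelina" if clade_b else "Culicina"
        species = f"{genus} sp{i + 1:02d}"
        specimen = f"SPEC{i + 1:02d}"
        base_insert = fresh_insert(mean, sd)
        n_var = int(rng.integers(cfg.variants_min, cfg.variants_max + 1))
        species_variants = [base_insert]
        while len(species_variants) < n_var:
            mutated = _mutate_variant(rng, species_variants[0], cfg.microsat_indel_prob)
            if mutated not in used_inserts:
                used_inserts.add(mutated)
                species_variants.append(mutated)
        freqs = np.sort(rng.dirichlet(np.full(n_var, 2.0)))[::-1]
        for seq, freq in zip(species_variants, freqs):
            variants.append(
                VariantRecord(species=species, specimen=specimen, seq=seq, frequency=float(freq))
            )
        flank_l = _random_insert(rng, cfg.flank_len, 0.5)
        flank_r = _random_insert(rng, cfg.flank_len, 0.5)
        entry_seq = flank_l + fwd + species_variants[0] + rev_site_template + flank_r
        lineage = {
            "order": "Diptera",
            "suborder": "Nematocera",
            "family": "Culicidae",
            "subfamily": "Anophelinae" if clade_b else "Culicinae",
        }
        entries.append(
            ReferenceEntry(
                taxon=TaxonRecord(accession=next_acc(), species=species, lineage=lineage),
                seq=entry_seq,
            )
        )

    mean_off, sd_off = cfg.offtarget_insert_len
    for family, n in cfg.offtarget_groups.items():
        lineage = OFFTARGET_LINEAGES.get(
            family, {"order": "Unknown", "suborder": "", "family": family}
        )
        lineage = {k: v for k, v in lineage.items() if v}
        for j in range(n):
            species = f"{family} sp{j + 1:02d}"
            insert = fresh_insert(mean_off, sd_off)
            site = list(fwd_off)
            n_extra = int(rng.integers(0, cfg.offtarget_extra_mismatches + 1))
            for pos in rng.choice(len(site) - 1, size=n_extra, replace=False):
                alternatives = [b for b in "ACGT" if b != site[pos]]
                site[pos] = alternatives[int(rng.integers(0, 3))]
            flank_l = _random_insert(rng, cfg.flank_len, 0.5)
            flank_r = _random_insert(rng, cfg.flank_len, 0.5)
            entry_seq = flank_l + "".join(site) + insert + rev_site_template + flank_r
            entries.append(
                ReferenceEntry(
                    taxon=TaxonRecord(accession=next_acc(), species=species, lineage=lineage),
                    seq=entry_seq,
                )
            )

    return ReferenceSet(entries), ReferenceLibrary(variants)


def _categories(config: PoolSimConfig) -> tuple[list[str], np.ndarray, list[str]]:
    """Category labels, probabilities and provenance kinds for one run."""
    spec_by_species = {s.species: s for s in config.specimens}
    target_mass = {
        sp: vol * spec_by_species[sp].amplifiability * spec_by_species[sp].degradation
        for sp, vol in config.design.volumes.items()
    }
    total_target = sum(target_mass.values())
    if total_target <= 0:
        raise ValueError("total target amplifiable mass is zero")
    # normalize target mass to 1 so bycatch_dna_ratio is in target-mass units
    target_mass = {sp: m / total_target for sp, m in target_mass.items()}

    bycatch_mass = config.bycatch_dna_ratio * config.bycatch_unit_mass
    contaminant_mass = bycatch_mass * config.carryover_fraction
    true_bycatch_mass = bycatch_mass - contaminant_mass

    labels: list[str] = []
    masses: list[float] = []
    kinds: list[str] = []
    for sp, m in target_mass.items():
        labels.append(sp)
        masses.append(m)
        kinds.append("target")
    if contaminant_mass > 0:
        contaminated = config.contaminated_species or tuple(config.design.volumes)
        share = contaminant_mass / len(contaminated)
        for sp in contaminated:
            labels.append(f"contaminant::{sp}")
            masses.append(share)
            kinds.append("contaminant")
    if true_bycatch_mass > 0:
        weights = dict(config.bycatch_family_weights)
        wsum = sum(weights.values())
        for family, w in weights.items():
            labels.append(f"bycatch::{family}")
            masses.append(true_bycatch_mass * w / wsum)
            kinds.append("bycatch")
    p = np.array(masses, dtype=float)
    p /= p.sum()
    return labels, p, kinds


def true_proportions(config: PoolSimConfig) -> dict[str, float]:
    """Expected read proportions per category.

    Target species get mass volume x amplifiability x degradation
    (normalized to 1 across the pool); bycatch families and carryover
    contaminants (labelled ``bycatch::family`` / ``contaminant::species``)
    are folded in via ``bycatch_dna_ratio`` and ``carryover_fraction``.
    """
    labels, p, _ = _categories(config)
    return dict(zip(labels, p.tolist()))


def simulate_reads(config: PoolSimConfig) -> SimulatedRun:
    """Draw one pooled sequencing run.

    Raw depth ``round(N / (1 - quality_loss))`` is thinned binomially at the
    quality-loss rate, then the surviving reads are distributed
    multinomially over the true category proportions.  Carryover
    contaminant reads are merged into their species' read-table entry (they
    are indistinguishable in real data); provenance tallies keep the truth.
    """
    labels, p, kinds = _categories(config)
    rng = np.random.default_rng(config.seed)
    ql = config.quality_loss
    raw_depth = int(round(config.depth / (1 - ql))) if ql > 0 else config.depth
    discarded = int(rng.binomial(raw_depth, ql)) if ql > 0 else 0
    realized = raw_depth - discarded
    counts = rng.multinomial(realized, p)

    read_table: dict[str, int] = {sp: 0 for sp in config.design.volumes}
    bycatch_counts: dict[str, int] = {}
    provenance = {"target": 0, "bycatch": 0, "contaminant": 0}
    for label, kind, c in zip(labels, kinds, counts):
        c = int(c)
        provenance[kind] += c
        if kind == "target":
            read_table[label] += c
        elif kind == "contaminant":
            sp = label.split("::", 1)[1]
            read_table[sp] = read_table.get(sp, 0) + c
        else:
            family = label.split("::", 1)[1]
            bycatch_counts[family] = bycatch_counts.get(family, 0) + c
    return SimulatedRun(
        pool_id=config.design.pool_id,
        read_table=read_table,
        bycatch_counts=bycatch_counts,
        provenance=provenance,
        true_proportions=dict(zip(labels, p.tolist())),
        depth_requested=config.depth,
        raw_depth=raw_depth,
        realized_depth=realized,
        seed=config.seed,
    )


def sample_read_sequences(
    run: SimulatedRun,
    library: ReferenceLibrary,
    bycatch_inserts: Mapping[str, Sequence[str]],
    seed: int,
) -> tuple[list[str], list[str]]:
    """Materialize a run's counts as primer-trimmed read sequences.

    Target (and merged carryover) reads sample each species' library
    variants by within-individual frequency; bycatch reads sample the
    family's insert pool (sequences absent from the library, hence
    unassignable under exact identity).  Returns ``(reads, truth_labels)``
    with labels ``species`` or ``bycatch::family``.
    """
    rng = np.random.default_rng(seed)
    reads: list[str] = []
    labels: list[str] = []
    for sp, count in run.read_table.items():
        if count == 0:
            continue
        variants = library.variants_of(sp)
        if not variants:
            raise KeyError(f"species {sp!r} has no library variants")
        freqs = np.array([v.frequency for v in variants], dtype=float)
        freqs /= freqs.sum()
        picks = rng.choice(len(variants), size=count, p=freqs)
        reads.extend(variants[int(k)].seq for k in picks)
        labels.extend([sp] * count)
    for family, count in run.bycatch_counts.items():
        pool = list(bycatch_inserts.get(family, ()))
        if not pool:
            raise KeyError(f"no bycatch insert pool for family {family!r}")
        picks = rng.integers(0, len(pool), size=count)
        reads.extend(pool[int(k)] for k in picks)
        labels.extend([f"bycatch::{family}"] * count)
    return reads, labels


def make_fresh_pool_design(
    pool_id: str,
    species: Sequence[str],
    seed: int,
    v_min: float = 0.5,
    v_max: float = 40.0,
) -> PoolDesign:
    """A mock pool with per-specimen volumes log-uniform on [v_min, v_max] µL.

    Spans the two-orders-of-magnitude contribution range of the emulated
    fresh pools (0.5–40 µL).
    """
    rng = np.random.default_rng(seed)
    vols = np.exp(rng.uniform(np.log(v_min), np.log(v_max), size=len(species)))
    return PoolDesign(pool_id=pool_id, volumes=dict(zip(species, vols.round(2))))


def make_specimens(
    species: Sequence[str],
    seed: int,
    amplifiability_log_sd: float = 0.5,
    degradation: float | Sequence[float] = 1.0,
) -> list[SpecimenModel]:
    """Specimen models with log-normal amplifiability heterogeneity."""
    rng = np.random.default_rng(seed)
    amps = np.exp(rng.normal(0.0, amplifiability_log_sd, size=len(species)))
    if np.isscalar(degradation):
        degr = [float(degradation)] * len(species)
    else:
        degr = [float(d) for d in degradation]
    return [
        SpecimenModel(species=sp, amplifiability=float(a), degradation=d)
        for sp, a, d in zip(species, amps, degr)
    ]


def simulate_fresh_pools(
    species: Sequence[str],
    specimens: Sequence[SpecimenModel],
    n_pools: int,
    depth: int,
    seed: int,
    quality_loss: float = 0.20,
) -> tuple[list[PoolDesign], list[SimulatedRun]]:
    """Simulate replicate culicid-only pools with independent volume designs."""
    designs = []
    runs = []
    for i in range(n_pools):
        design = make_fresh_pool_design(
            pool_id=chr(ord("A") + i), species=species, seed=seed * 1000 + i
        )
        config = PoolSimConfig(
            design=design,
            specimens=list(specimens),
            depth=depth,
            quality_loss=quality_loss,
            seed=seed * 1000 + 500 + i,
        )
        designs.append(design)
        runs.append(simulate_reads(config))
    return designs, runs
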