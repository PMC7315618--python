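# Methods

## Scope and model overview

ampliscope models the computational half of a clade-restricted metabarcoding
study: (1) predicting which reference sequences a degenerate primer pair will
amplify, (2) summarizing primer coverage and the taxonomic information content
of the predicted amplicons, (3) assigning pooled reads to species by exact
identity against a per-specimen variant library, and (4) asking whether read
counts from mock DNA pools are a linear, unbiased readout of input volume.
A seeded generative model supplies both the reference sequences and the pooled
read counts, so every claim the package makes can be tested end to end against
known ground truth.

## In-silico PCR

A primer is an IUPAC string written 5′→3′. A primer base and a template base
*match* when their IUPAC sets intersect; consequently an `N` in the template
never counts as a mismatch. A window is a binding site when the number of
non-matching positions is at most `max_mismatches` (default 5 per primer,
counted over the whole oligo; a 3′-terminal mismatch counts here too — one
event, two consequences). Both strands are scanned; coordinates are always
0-based half-open on the forward strand, and `site_seq` is stored in primer
orientation so logo columns align with primer positions.

The 3′-anchor criterion: a mismatch at the primer's 3′-terminal base is
treated as precluding polymerase extension. Sites failing it are still
*reported* (flagged `three_prime_match=False`) because the 3′ column is the
most informative part of a coverage logo, but under the strict policy
(`require_three_prime=True`, the default) they cannot anchor a product. The
criterion window is 1 base by default and widenable via `three_prime_window`.

Products: every convergent forward/reverse site pair with primer-inclusive
length ≤ `max_amplicon_length` (default 2000 nt — an explicit cap chosen for
this implementation, wide enough to never truncate a D2-scale amplicon) is
emitted, with no shortest-product collapsing; metrics deduplicate per
accession where a per-entry answer is needed. Sites may overlap; ties are not
merged. Correctness is checked against an independently written brute-force
enumerator on random degenerate templates, and by a strand-symmetry property
(reverse-complementing every template leaves the product set unchanged).

## Coverage, logos, resolution

Position count matrices are integer 5×L tables (A/C/G/T plus an `other` row
for degenerate template bases — integer counts keep the column-sum invariant
exactly testable; no fractional allocation). One site per accession is counted
(lowest mismatch count, then leftmost) so entries with several candidate
windows do not dominate.

Species resolution is implemented in two modes because the field uses both
denominators: `species-unique` (default) scores a species as resolved iff none
of its distinct insert sequences is shared with another species, and divides
by species with at least one hit; `amplicon-lca` divides inserts produced by
exactly one species by all distinct inserts. `shared_species_subset` restricts
two hit sets to their common species so scores are comparable across primer
sets with different coverage. Amplicon statistics use the sample SD (n−1)
throughout; a single-observation group reports SD as NaN rather than 0.

## Assignment

The variant library maps species → primer-trimmed amplicon variants with
within-individual frequencies. Variants below 1% of a specimen's reads are
removed before library construction (strict less-than, so a variant at
exactly 1% survives); the cutoff targets cross-specimen contamination in
bulk-collected material. Assignment is exact string identity after uppercase
normalization over the full read — no substring or near-match logic — because
reads are primer-trimmed full amplicons and near-matching would blur the
contamination signal the library filter exists to remove. Read counts are
summed per species across that species' variants. A sequence occurring under
two species is a hard construction error, since it would make exact-identity
assignment ambiguous.

## Pool quantification

For volumes v and reads r over the designed species, the normalized profile is
(r_i/v_i) rescaled to sum 1; rescaling (rather than raw per-µL rates) makes
pools of different depth comparable, which is what all downstream comparisons
need. Zero-read species stay in the profile at 0, and contribute 0 (not
missing) to the Best Estimate and regressions — dropout is information, not
missing data. The Best Estimate is the unweighted mean of the normalized
profiles of replicate pools.

Two regressions answer two different questions:

* *Is output linear in input?* Read **share** (r_i/Σr) against design share
  (v_i/Σv). Under equal amplifiability the expectation is exactly the design
  share, so slope → 1 and intercept → 0. Note the volume-*normalized* profile
  cannot carry this signal: dividing by volume makes it flat when
  amplifiability is equal, by construction.
* *Is a pool consistent with its replicates?* The pool's normalized profile
  against the Best Estimate (volume cancels on both axes; slope ≈ 1 when the
  pool behaves like its replicates).

Both use ordinary least squares (the reported quantities are the standard
regression line's slope and y-intercept), a two-sided Pearson test on the
same values as fitted, and a Bonferroni threshold α/m with m defaulting to
the number of fits in one batch invocation. Dropout probability at depth N
and proportion p is the exact multinomial marginal (1−p)^N, cross-checked
against Monte-Carlo zero-read rates in the test suite.

## The generative model

`synth_reference_set` plants the clade-diagnostic structure the primer pair
was designed around: every entry carries the conserved reverse priming site;
target entries carry the exact forward site (3′-C included); off-target
entries carry the forward site with the 3′ base mutated C→T plus up to two
internal substitutions. Thus strict in-silico PCR recovers 100% of the target
and 0% of the off-target clade *by construction*, which is the planted truth
the recovery tests assert. Defaults mirror the emulated study conditions:
17 target species (14 short-insert at 383 ± 9 nt, 3 long-insert at
432 ± 24 nt, both at 60% GC), 1–6 within-individual variants per specimen
(SNPs and 2-nt microsatellite-slippage indels), 40-nt flanks (comfortably
over the 30-bp flank filter), and six off-target families spanning the
standard bycatch bins.

`simulate_reads` draws raw depth N/(1 − quality_loss), removes a
Binomial(raw, quality_loss) fraction (default 0.20, the typical share of
output lost to quality filtering), and distributes the survivors
multinomially over category proportions ∝ volume × amplifiability ×
degradation for target species, plus bycatch mass `bycatch_dna_ratio ×
bycatch_unit_mass` split between true bycatch families (one dominant,
default 70% Chaoboridae-like) and carryover contamination assigned uniformly
to a configurable subset of target species. Carryover reads are merged into
their species' read-table counts (they are indistinguishable in real data);
provenance tallies retain the truth. Degradation is a scalar multiplier on
amplifiable template per specimen, not length-dependent fragmentation — the
simplest mechanism consistent with the observation that degraded pools
preserve relative profiles; the degradation rate itself is a free parameter,
as no quantitative decay rate is available for field-realistic storage.

Counts are multinomial given fixed proportions: no PCR branching-process
overdispersion, no per-base sequencing error, no chimeras. Passing tests
therefore demonstrate correctness of the analysis pipeline under an idealized
library, not robustness to PCR stochasticity or denoising artifacts in real
data. `sample_read_sequences` materializes counts as error-free variant
sequences, which is what makes the assignment invariant (unassigned reads ≡
bycatch reads) exact.

## Problem sizes and numerical choices

The shipped simulations use 17-species pools at 17,000 reads (fresh-pool
regime), 3,050–3,400 reads (low-coverage/degraded regime) and 100,000 reads
for slope recovery; recovery checks run over 20 seeds and the engine/oracle
equivalence over 200 random templates ≤ 400 nt — sizes at which every suite
completes in seconds while standard errors are far inside the asserted
tolerances. Normalization sums are exact to 1e−12; regression uses
`scipy.stats.linregress`; a zero-variance x is an explicit error rather than
a NaN fit. GC content counts G, C and S (the only code unambiguously G/C);
other ambiguity codes count toward length only. All generators derive from
`numpy.random.default_rng(seed)`; derived seeds are small offsets of the
user's seed.

## Known limitations

No thermodynamic (ΔG/melting) primer model — matching is purely
combinatorial. No primer *design* search; the package evaluates given pairs.
Taxonomy is a flat rank→name table (sufficient for rank-equality bins; no
tree reasoning). Reads are consumed post-merging/denoising; upstream FASTQ
processing is out of scope. Resolution modes bracket, but cannot settle,
how intraspecific variants should be counted — that choice is reported with
every score.
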