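# Methods notes

## Insertion-site model

The integration model is PiggyBac-like: the transposase excises an
ITR-flanked cargo and inserts it at TTAA host tetramers, leaving a
target-site duplication because its cut is staggered. We model the
duplication length as a configurable offset `d` with default 5, and report
every event at the two positions it supports: `posL = n` (the 1-based first
base of the duplicated tract) and `posR = n + d`. The biology of a 4-base
TTAA target versus a 5-base duplication is not reconciled here; `d` is a
parameter and the two-position criterion is what the caller implements.
Endogenous occurrences of the 20-nt inverted-repeat motif
(`GATTATCTTTCTAGGGTTAA`) produce junction-like evidence at a single
position only; the absence of a partner at distance `d` is what lets the
caller file them as artefacts.

## Pipeline stages and their contracts

1. **Duplicate removal** keys on the ordered (mate1, mate2) sequence tuple
   and keeps the first occurrence. Mate-swapped pairs count as distinct;
   the operation is idempotent.
2. **IR trimming** locates the motif — in full anywhere in the read, or as
   a 3′-terminal prefix of at least 10 nt for reads ending inside the IR —
   allowing `max_mismatch` substitutions (default 0), and removes the match
   and everything 3′ of it. Cutting repeats to a fixpoint, which makes the
   operation idempotent by construction (a single pass can leave a retained
   part that itself ends in a qualifying motif prefix). Both mates of every
   pair are searched.
3. **Junction selection** keeps pairs in which at least one mate was
   trimmed to ≤ L − L_IR (131 nt at the defaults). Partial-IR trims above
   the threshold (e.g. a read trimmed to 140 nt) do not qualify; this is
   applied before mapping.
4. **Mapping** is exhaustive within a 0–1 mismatch budget. Candidate
   placements come from pigeonhole seeding (a read with ≤ k mismatches
   contains one of k+1 exact segments, located with substring search) and
   are then verified, which finds exactly the set of placements an
   all-offset scan would. A read is `unique` iff a single placement attains
   the minimum mismatch count over both strands of all chromosomes; ties
   are `ambiguous`. This plays the role a mapping-quality cutoff plays for
   heuristic aligners, but uniqueness here is exact, so no numeric quality
   is computed. Pairs are kept when both mates are unique, co-chromosomal
   and within a 1,000 bp span (a documented default, configurable).
5. **Junction extraction**: with the IR trimmed from the 3′ end, a
   forward-strand placement abuts the IR at `start + length − 1`, a
   reverse-strand placement at `start`.
6. **Calling** pools candidates per (chromosome, position) across strands —
   the criterion is positional — and pairs positions at distance `d` left
   to right, each side needing `min_support` reads (default 1; no threshold
   is inherent to the criterion). Event strand is the majority strand of
   supporting reads, ties to "+". Unpaired supported positions go to the
   artefact report.
7. **Annotation** labels each event with every overlapping top-level
   feature (Exon if the event touches one of the feature's exons, else
   Intron), or Intergenic; stacked features each produce a row. Events on
   chromosomes unknown to the annotation raise with the unmatched names.

## Synthetic data: what it emulates and what it does not

The generator stands in for a real sequencing experiment at desk scale:
random ACGT chromosomes of tens of kilobases (TTAA guaranteed at least once
per 5 kb), verbatim IR decoys planted away from chromosome ends, junction
pairs with the IR at the junction mate's 3′ end followed by random
transposon cargo, an anchor mate of pure genome within 500 bp, exact-copy
PCR duplicates at `dup_rate`, and uniform substitution errors at
`error_rate` per base outside the IR copy. Left-flank junction mates are
forward-strand and end at `n`; right-flank mates are reverse-strand and
start at `n + d` — together they produce the two-position signature.
Read-length (151), motif (20 nt) and offset (5) follow the assay geometry;
depth 10 and error rate 0.001 are defaults chosen for fast, unambiguous
desk-scale runs. Growth simulation is deterministic exponential
compounding with exact-fraction passaging, because the expected-composition
arithmetic it feeds is deterministic; a stochastic birth-death option is
deliberately out of scope.

Not emulated: realistic human-genome composition (repeats, GC structure),
indels, quality-score profiles, library-prep biases, chimeric fragments.
Passing tests therefore demonstrate the correctness of the algorithms'
logic and coordinate arithmetic, not robustness to the full error spectrum
of real libraries.

## Dynamics conventions

CPD is log₂(N_final/N_seed), reading the printed-formula denominator as
log₁₀(2) — the standard population-doubling definition. Deviations between
observed and expected compositions are reported both as percentage points
(observed − expected) and as ratios, with an infinity flag when the
expected fraction is zero. Whether expected curves should compound fixed
day-0 single-culture rates or rates re-estimated each passage is left to
the caller: `expected_composition`/`expected_timecourse` compound fixed
rates, and per-interval rates from `cpds_from_growth` can be chained for
the stepwise variant; neither mode is privileged. The mix-invasion ratio
normalizes per-seeded-cell invasion in a mixture against the clone alone;
a clone contributing half the seeded cells but matching its solo invader
count scores 2.0. Tumor volume is the caliper formula D·d²/2 with D ≥ d
enforced.

## STR matching conventions

Matching is reference-anchored: the denominator is the total allele count
of the reference database entry, the numerator sums per-locus set
intersections, and loci present only in the sample are ignored. Percent
match is truncated, not rounded (14/16 → 87), which is the only reading
consistent with a database that prints 87% for that fraction. Homozygous
reference loci contribute one allele; a reference heterozygote matched on
one allele contributes one. The Amelogenin sex marker's "x" is an ordinary
allele label. Two-way similarity scores (Masters, Tanabe) are out of scope.

## Numerical and testing choices

All coordinates are 1-based inclusive; FASTA/FASTQ/GFF3 io goes through
Biopython and gffutils, tables through pandas. Test problem sizes are
40–100 kb genomes, ≤ 10 events, depth ≤ 10, and 200-read mapper
comparisons, which keep the whole suite and the reproduction script within
seconds while leaving placements overwhelmingly unique. The mapper's
correctness is checked against an independent numpy all-offset oracle kept
in the test suite; growth-parameter recovery is asserted to 1e-9 (floating
arithmetic on exact exponential compounding). Composition states validate
that fractions sum to 1 within 1e-9. Degenerate inputs are defined
behavior: empty FASTQ input yields an empty event table and a zero-count
log; a read consisting of the IR alone trims to length 0 and is dropped
before mapping; all-zero stress survival and non-positive cell counts
raise.

## Known limitations

The exhaustive mapper is for desk-scale genomes (≤ ~1 Mb), not hg19-scale
work — the contract (exact uniqueness) is the point, not throughput.
Multi-IR constructs, structural variation around insertion sites, and
support-weighted event scoring are not modeled. The event-calling greedy
left-to-right pairing can in principle mis-pair chains of positions at
exact `d` spacing, which do not arise under the generator's separation
constraints and would be pathological in real data.
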