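# Methods

## Repeat-array detection

The scanner is a scored seed-and-extend search in the Sputnik family.
Every position of a sequence seeds a candidate unit of each requested
size k ∈ {2..6}; seeds whose unit is non-primitive (a tandem of a
shorter unit) or merely repeats the preceding period are skipped, the
latter because they can only produce dominated sub-arrays of the seed
one period earlier. A candidate is extended base by base against a
perfect tiling of its unit: match +1, mismatch −6 (Sputnik's classic
weights), with an N terminating the extension unconditionally. The
reported candidate is the prefix maximising the cumulative score (ties
go to the longer prefix); extension stops once the score falls 30 below
its running maximum, a point from which no array can recover the
default purity threshold. Candidates must reach score ≥ 8, repeat count
≥ `min_repeats` (default 6) and purity ≥ `min_purity` (default 0.9),
where purity is the fraction of bases agreeing with the perfect tiling.
Overlaps are resolved greedily — score desc, length desc, leftmost,
then unit — yielding deterministic, maximal, non-overlapping arrays.

Because the comparison is against a fixed tiling of the seed unit, a
single insertion or deletion inside an array phase-shifts everything
downstream and the array is reported as its perfect parts; there is no
indel-recovery branch. This is a deliberate simplification: it keeps
the algorithm exactly equal to an exhaustive substring-scoring oracle
(asserted on 1,000 seeded random sequences in the test suite), and for
amplicon genotyping a split array simply contributes its dominant
perfect run.

Only the forward strand is scanned; strand and rotation are unified at
reporting time by the canonical motif — the lexicographic minimum over
all rotations of the unit and of its reverse complement — and catalog
summaries report both raw-unit and canonical-unit tallies, since
published abundance fractions differ between conventions.

## Demultiplexing

Reads are assumed to follow the four-primer construct
`[protective 4][index 10][M13][target primer][insert]` on both mates.
The sample is resolved from the 10-base index at offset 4 (mate 1
first, mate 2 as fallback) within `index_mm` mismatches (default 1); a
tie at the minimal distance is ambiguous, never a call. The locus is
resolved from the target primer located after the M13 tail (matched
with ≤ 2 mismatches); if the tail cannot be anchored, the first 45
bases are scanned for the primer directly. Orientation is normalised so
the forward primer leads mate 1. On success the technical prefix is
trimmed from both mates, and read-through into the far primer is cut at
the reverse-complemented far-primer anchor. Protective bases are
skipped by offset, not matched — they are synthesis protectors, not
identifiers. With indices of pairwise Hamming distance ≥ 2·`index_mm`+2
a read with at most `index_mm` index errors can never be assigned to
the wrong sample; the simulator draws indices at distance ≥ 4 and the
suite asserts zero cross-sample assignments at the defaults.

Classification is cached on the technical prefix of both mates — a pure
optimisation exploiting amplicon duplication.

## Read merging

Mate 2 is reverse-complemented and every relative shift of the two
reads is scored as matches − mismatches, computed for all shifts at
once by a four-channel correlation. Shifts with overlap ≥ `min_overlap`
(default 10) compete; the best-scoring shift wins (ties: standard
geometry before staggered, then longer overlap), and the merge is
accepted iff the overlap's mismatch fraction is ≤ `max_mismatch_frac`
(default 0.25). Consensus takes the base with the higher Phred score at
disagreements (ties to mate 1) with quality |q1 − q2|, and the maximum
quality at agreements.

Two geometries arise. In the standard one the merged read is
mate 1's head + consensus + mate 2's tail, and merged length equals
len1 + len2 − overlap. In the *staggered* geometry the insert is
shorter than the trimmed reads: each mate runs 1–19 bp into the far
primer — too little for the demux anchor, which needs the full
primer — so the flipped mate 2 begins *before* mate 1. The overlap is
then the insert itself and the overhangs are technical read-through,
which is discarded; the merged read is the consensus alone. Without
this branch, inserts in a ~20 bp window below the trimmed read length
cannot be merged at all. The behavioural invariant — an error-free pair
simulated from an amplicon reconstructs it exactly — holds in both
geometries and is asserted across the full length range.

This stage replaces a maximum-likelihood merger with a deterministic
score criterion; it makes no claim to PEAR's statistics.

## Genotype calling

Each expected repeat array of an amplicon is its own locus
(`amplicon#ordinal`), so indels in the sequence between arrays cannot
shift a neighbouring array's allele. Arrays found in a merged read are
matched to the expected ordinals by canonical motif in order of
appearance; reads lacking an expected array are tallied as unscored.
The allele is the array length in bp (it need not be a multiple of the
unit), and depths are keyed by that length.

The decision cascade, all thresholds configurable:

1. total depth < `min_total_depth` (10) → missing;
2. drop lengths below `min_allele_frac` (0.05) of total depth;
3. a retained length exactly `stutter_gap` (1) repeat units *below* a
   deeper retained length, with at most `stutter_max_frac` (0.5) of its
   depth, is flagged PCR stutter and dropped;
4. heterozygous (L1, L2) iff the second-deepest survivor reaches
   `het_ratio` (0.3) of the deepest, else homozygous (L1, L1);
5. three or more survivors above the ratio → ambiguous, left for
   curation.

The numeric defaults are conventional starting points, not a claimed
reproduction of any published screen; they are surfaced in the rules
config precisely because real screens tune them. All cascade thresholds
except the depth floor are fractions, so calls are invariant under
rescaling all depths; the depth floor necessarily breaks that
invariance for tables below it. Raising the second allele's depth can
only move a call toward heterozygosity. The curation report lists the
complete length:depth spectrum per call; an edits table can override
calls, and an override naming a length absent from the spectrum is
rejected.

## Population-genetic summaries

With allele frequencies p over the 2n gene copies of non-missing calls
(missing genotypes are dropped per locus):

- Ho = heterozygous / genotyped;
- He = 1 − Σp² (uncorrected — the convention under which He and
  Ae = 1/Σp² satisfy He = 1 − 1/Ae exactly, an identity the suite
  asserts on every locus of every run; Nei's unbiased 2n/(2n−1) variant
  is available via `unbiased_he`);
- PIC (Botstein) = 1 − Σp² − Σ_{i<j} 2 p_i² p_j²;
- exact Hardy–Weinberg test conditional on allele counts: the
  probability of genotype table {n_ij} is
  n! / Π n_ij! · 2^h · Π m_i! / (2n)!, with h the heterozygote count
  and m_i the allele counts, and the p value sums tables no more
  probable than the observed one (relative tolerance 1e-9 on
  log-probabilities). Tables are enumerated exhaustively when at most
  10⁶ exist (forced assignments prune the search); otherwise the null
  is sampled by seeded random re-pairing of the observed gene copies
  (default 100,000 draws) with the (hits+1)/(reps+1) estimator, which
  keeps p in (0, 1]. The exact test is conservative: under simulated
  random mating its rejection rate at α = 0.05 stays at or below α,
  which the suite checks.

Report tables round half-up to 2 decimals, flag monomorphic loci, and
average over polymorphic loci only in the mean row.

## Ks summaries and dating

Ks values at or above a saturation cap (0.6 between species, 3.5 within
a genome, configurable) are excluded. The peak is the argmax of a
Gaussian KDE (Silverman bandwidth by default) on a 2048-point grid over
[0, cap), reported to 3 decimals and requiring ≥ 10 capped values.
Silverman's bandwidth depends on sample size, so the peak is invariant
under duplication of the sample only at a fixed bandwidth factor.

Dating uses the single-path convention T = Ks / r by default, with the
per-lineage convention T = Ks / (2r) behind a flag; rate estimation is
the same identity solved for r. The two are exact inverses, asserted to
machine precision.

## Simulator

The generator emulates the screening design the pipeline targets:
32 diploid individuals, 250-bp paired-end reads, amplicons of one or
two repeat arrays flanked by 40-bp non-repetitive segments, ~500× mean
per-bin depth (negative-binomial, shape 5, matching the uneven per-bin
depths of pooled amplicon libraries), single-unit stutter at a
configurable per-read probability with loss:gain 4:1, and uniform
per-base substitution error (default runs use 0.005 where noise is
wanted). Genotypes are drawn by random mating from per-array allele
frequencies; both arrays of a read come from one simulated haplotype.
Everything derives from one seeded generator, so outputs are
byte-identical across runs.

Two construction constraints keep truth well-defined: allele pools are
spaced two repeat units apart, so a single stutter step cannot turn one
true allele into another; and the flank base adjacent to an array never
continues the repeat pattern, otherwise the scanner would (correctly)
absorb it and every allele would shift by one base. Real flanking
sequence offers no such guarantee — a real amplicon whose flank extends
the repeat simply defines its allele one base longer, consistently
across individuals, which leaves polymorphism intact. The simulator
also omits chimeras, index hopping, quality degradation along the read,
and indel sequencing errors; passing tests therefore demonstrate
correctness of the decision logic under the modelled noise, not
robustness to every artefact of real libraries.

Problem sizes in the test suite — 1,000 sequences for the
scanner/oracle equivalence, 32 × 20 loci at ~500× for noisy genotype
recovery, 300 replicates for test calibration — were chosen as the
smallest runs that exercise each property convincingly.

## Known limitations

- No indel model in the repeat scan (see above) and no indel
  sequencing-error model in the simulator.
- The exact-HWE Monte Carlo path requires an explicit seed; there is no
  global random state.
- The merger's staggered geometry discards overhangs rather than
  reporting them; pairs whose insert is shorter than `min_overlap`
  cannot be merged.
- GenePop export uses 3-digit allele codes and therefore requires
  allele lengths < 1000 bp.
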