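# ampligeno

Microsatellite (SSR) genotyping from pooled, indexed amplicon sequencing
reads, for researchers developing co-dominant markers in non-model
species.

Amplicon libraries built with a tailed two-round PCR carry a technical
prefix on every read — 4 protective bases, a 10-base sample index, the
M13 universal tail, and the locus-specific primer — followed by the
genomic insert. `ampligeno` turns such paired-end FASTQ files into a
per-locus marker characterisation table:

1. **demux** — assign each read pair to its (sample, locus) bin by
   Hamming-tolerant index and primer matching, trim the technical
   sequence, and normalise mate orientation;
2. **merge** — merge mates into a single amplicon sequence by
   score-maximising overlap with Phred-weighted consensus;
3. **genotype** — detect repeat arrays in every merged read with a
   scored tandem scan (seed-and-extend, match +1 / mismatch −6), treat
   each array of an amplicon as its own locus, and call genotypes from
   the depth-per-array-length spectrum with a deterministic cascade
   (depth floor, allele-fraction filter, single-unit PCR-stutter filter,
   heterozygote depth ratio); an allele is the repeat-array length in bp;
4. **popgen** — per-locus summaries: observed allele count Ao, effective
   allele number Ae = 1/Σp², observed heterozygosity Ho, expected
   heterozygosity He = 1 − Σp², Botstein's polymorphism information
   content PIC = 1 − Σp² − ΣΣ 2p²q², and an exact Hardy–Weinberg test
   conditional on allele counts (full enumeration of genotype tables, or
   seeded Monte Carlo when the table space is too large).

A companion module summarises synonymous-substitution (Ks)
distributions — median and kernel-density peak below a saturation
cap — and converts between Ks, substitution rate r and divergence time
(T = Ks/r by default, T = Ks/2r with `--per-lineage`).

A seeded simulator (`ampligeno.synthetic`) generates complete
experiments — diploid genotypes drawn under Hardy–Weinberg, reads with
the four-primer construct, negative-binomial depth, single-unit PCR
stutter (loss favoured 4:1) and uniform sequencing error — and is the
ground truth behind the test suite.

## Worked example

Simulate a 32-individual screen and run the full pipeline:

```
ampligeno simulate --seed 5 --outdir demo/sim
cat > demo/run.yaml <<EOF
r1: demo/sim/r1.fastq
r2: demo/sim/r2.fastq
scheme: demo/sim/scheme.tsv
locus_motifs: demo/sim/locus_motifs.tsv
outdir: demo/out
seed: 7
EOF
ampligeno run --config demo/run.yaml
```

`demo/out/locus_summary.tsv` then contains one row per repeat-array
locus (this is the actual output of the commands above):

```
locus    alleles     n   Ao   Ae    Ho    He    PIC   HWE_p  note
Amp01#1  24, 30, 36  32  3.0  2.62  0.66  0.62  0.54  0.85
Amp01#2  24, 28, 32  32  3.0  2.50  0.53  0.60  0.52  0.67
Amp02#1  30, 36, 42  32  3.0  2.82  0.75  0.65  0.57  0.31
...
Mean                     3.0  2.80  0.66  0.64  0.56         mean over 6 polymorphic loci
```

Amp01 carries two repeat arrays, so it yields two independent loci
(`#1`, `#2`). Alleles are array lengths in bp; `Ho`/`He` are observed
and expected heterozygosity, `PIC` the marker informativeness, and
`HWE_p` the exact Hardy–Weinberg p value — none of the loci here
deviates from equilibrium, as expected for genotypes simulated under
random mating. `demo/out/genotypes.tsv` holds the per-individual calls
and `demo/out/curation_report.tsv` the full length:depth spectrum
behind every call, for manual review (`ampligeno genotype --edits`
applies curation edits). `manifest.json` records parameters, input
checksums and per-stage read counts.

Other subcommands: `find-ssrs` (mine repeat arrays from FASTA),
`demux`, `merge`, `genotype`, `popgen` (per-stage entry points), and
`ks-date`:

```
ampligeno ks-date --ks-table pairs.tsv --cap 0.6 --rate 3.1e-9
```

prints the capped median and density peak of the Ks sample plus the
implied divergence times.

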