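"""Synthetic amplicon-sequencing experiments with known ground truth.

The generator emulates an indexed microsatellite amplicon library: for
every sample and amplicon it draws a diploid genotype by random mating
from configured allele frequencies, then emits paired-end reads with
the four-primer construct layout

    [4 protective][10 index][M13 tail][locus primer][insert][...tails]

on both ends, PCR stutter on repeat arrays (single-unit slippage, loss
favoured over gain), negative-binomially distributed per-bin depth, and
uniform per-base sequencing error.  Everything is driven by one seeded
generator, so a configuration reproduces byte-identical FASTQ output.

Amplicons may carry more than one repeat array; the two arrays of a
read always come from the same simulated haplotype, and per-array
allele lengths are recorded independently in the truth tables.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import revcomp
from .repeat_finder import canonical_motif
from .scheme_demux import (
    DEFAULT_M13,
    IndexEntry,
    LocusDef,
    PrimerScheme,
    write_scheme,
)

_BASES = "ACGT"

#: constant Phred quality written for simulated bases (Q40)
_QUAL_CHAR = "I"


@dataclass(frozen=True)
class SimLocus:
    """One amplicon: primers, repeat arrays and their allele pools."""

    name: str
    fwd_primer: str
    rev_primer: str
    motifs: tuple[str, ...]  # repeat units in order of appearance
    flanks: tuple[str, ...]  # len(motifs) + 1 segments around the arrays
    allele_pools: tuple[dict[int, float], ...]  # per array: length_bp -> freq

    def __post_init__(self) -> None:
        if len(self.flanks) != len(self.motifs) + 1:
            raise ValueError(f"{self.name}: need one flank more than motifs")
        for pool in self.allele_pools:
            if abs(sum(pool.values()) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: allele frequencies must sum to 1")

    def array_locus_names(self) -> list[str]:
        return [f"{self.name}#{i + 1}" for i in range(len(self.motifs))]


@dataclass
class SimConfig:
    """Study conditions for a simulated genotyping experiment."""

    scheme: PrimerScheme
    loci: list[SimLocus]
    n_samples: int
    seed: int
    depth_mean: float = 500.0
    depth_dispersion: float = 5.0  # NB shape; variance = mu + mu^2 / shape
    stutter_prob: float = 0.0  # per read per array single-unit slippage
    stutter_loss_ratio: float = 4.0  # loss : gain odds
    error_rate: float = 0.0  # per-base substitution probability
    read_len: int = 250

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if len(self.scheme.samples) < self.n_samples:
            raise ValueError("scheme has fewer indexed samples than n_samples")

    def locus_motifs(self) -> dict[str, list[str]]:
        """Amplicon -> ordered repeat units, as the genotyper expects."""
        return {l.name: list(l.motifs) for l in self.loci}


def _tile(unit: str, length: int) -> str:
    reps = -(-length // len(unit))
    return (unit * reps)[:length]


def _has_tandem(seq: str, max_unit: int = 6, min_reps: int = 3) -> bool:
    for k in range(1, max_unit + 1):
        for i in range(len(seq) - k * min_reps + 1):
            if seq[i : i + k] * min_reps == seq[i : i + k * min_reps]:
                return True
    return False


def random_nonrepetitive(rng: np.random.Generator, length: int) -> str:
    """Random ACGT string free of short tandem repeats (>= 3 copies)."""
    while True:
        seq = "".join(rng.choice(list(_BASES), size=length))
        if not _has_tandem(seq):
            return seq


def random_indices(
    rng: np.random.Generator, n: int, length: int = 10, min_dist: int = 4
) -> list[str]:
    """Sample indices with pairwise Hamming distance >= min_dist."""
    chosen: list[str] = []
    while len(chosen) < n:
        cand = "".join(rng.choice(list(_BASES), size=length))
        if all(
            sum(a != b for a, b in zip(cand, prev)) >= min_dist for prev in chosen
        ):
            chosen.append(cand)
    return chosen


_DEFAULT_MOTIFS = ("AC", "AG", "AT", "CT", "GT", "AAC", "GAT", "ATT", "AAAAC")


def default_config(
    seed: int,
    n_samples: int = 32,
    n_loci: int = 5,
    depth_mean: float = 500.0,
    stutter_prob: float = 0.0,
    error_rate: float = 0.0,
    read_len: int = 250,
    n_two_array_loci: int = 1,
    alleles_per_locus: int = 3,
    flank_len: int = 40,
) -> SimConfig:
    """Build a complete, reproducible study configuration.

    Defaults emulate the screening design the pipeline targets:
    32 diploid individuals, 250-bp paired-end reads, ~500x per-bin mean
    depth, amplicons of one (occasionally two) repeat arrays with
    2-6 bp units and at least eight repeat units per base allele.
    """
    rng = np.random.default_rng(seed)
    indices = random_indices(rng, n_samples)
    samples = [
        IndexEntry(f"S{i + 1:02d}", indices[i], random_nonrepetitive(rng, 4))
        for i in range(n_samples)
    ]
    loci = []
    locus_defs = []
    for j in range(n_loci):
        name = f"Amp{j + 1:02d}"
        n_arrays = 2 if j < n_two_array_loci else 1
        motifs = tuple(
            str(rng.choice(_DEFAULT_MOTIFS)) for _ in range(n_arrays)
        )
        pools = []
        for unit in motifs:
            base = len(unit) * int(rng.integers(8, 13))
            # alleles two repeat units apart so stutter cannot bridge them
            lengths = [base + 2 * len(unit) * t for t in range(alleles_per_locus)]
            raw = rng.dirichlet(np.full(alleles_per_locus, 5.0))
            freqs = np.round(raw, 3)
            freqs[-1] = 1.0 - freqs[:-1].sum()
            pools.append({l: float(f) for l, f in zip(lengths, freqs)})
        # flank boundary bases must not continue the neighbouring repeat
        # pattern, or the scanned array would absorb them (allele lengths
        # are multiples of the unit, so the continuation base is unit[0]
        # on the right and unit[-1] on the left, for every allele and
        # single-unit stutter variant)
        flanks = []
        for f in range(n_arrays + 1):
            while True:
                cand = random_nonrepetitive(rng, flank_len)
                if f > 0 and cand[0] == motifs[f - 1][0]:
                    continue
                if f < n_arrays and cand[-1] == motifs[f][-1]:
                    continue
                break
            flanks.append(cand)
        flanks = tuple(flanks)
        fwd = random_nonrepetitive(rng, 20)
        rev = random_nonrepetitive(rng, 20)
        loci.append(
            SimLocus(name, fwd, rev, motifs, flanks, tuple(pools))
        )
        locus_defs.append(LocusDef(name, fwd, rev))
    scheme = PrimerScheme(loci=locus_defs, samples=samples, m13=DEFAULT_M13)
    return SimConfig(
        scheme=scheme,
        loci=loci,
        n_samples=n_samples,
        seed=seed,
        depth_mean=depth_mean,
        stutter_prob=stutter_prob,
        error_rate=error_rate,
        read_len=read_len,
    )


Haplotype = tuple[int, ...]  # one array length per array of the amplicon


@dataclass
class TrueGenotypes:
    """Simulated diploid truth: two haplotypes per (sample, amplicon)."""

    haplotypes: dict[tuple[str, str], tuple[Haplotype, Haplotype]] = field(
        default_factory=dict
    )

    def per_array_calls(self) -> dict[tuple[str, str], tuple[int, int]]:
        """Truth keyed by (sample, '<amplicon>#<ordinal>') as sorted pairs."""
        out = {}
        for (sample, amp), (h1, h2) in self.haplotypes.items():
            for i, (a, b) in enumerate(zip(h1, h2)):
                out[(sample, f"{amp}#{i + 1}")] = tuple(sorted((a, b)))
        return out

    def to_table(self):
        import pandas as pd

        rows = [
            {"sample": s, "locus": l, "allele1": a, "allele2": b}
            for (s, l), (a, b) in sorted(self.per_array_calls().items())
        ]
        return pd.DataFrame(rows, columns=["sample", "locus", "allele1", "allele2"])


def simulate_true_genotypes(config: SimConfig) -> TrueGenotypes:
    """Draw diploid genotypes by random mating (Hardy-Weinberg sampling)."""
    rng = np.random.default_rng(config.seed)
    truth = TrueGenotypes()
    samples = config.scheme.sample_names[: config.n_samples]
    for locus in config.loci:
        pools = [
            (list(pool.keys()), np.array(list(pool.values())))
            for pool in locus.allele_pools
        ]
        for sample in samples:
            haps = []
            for _ in range(2):
                hap = tuple(
                    int(lengths[rng.choice(len(lengths), p=freqs)])
                    for lengths, freqs in pools
                )
                haps.append(hap)
            truth.haplotypes[(sample, locus.name)] = (haps[0], haps[1])
    return truth


def _build_insert(locus: SimLocus, lengths: Sequence[int]) -> str:
    parts = [locus.flanks[0]]
    for unit, length, flank in zip(locus.motifs, lengths, locus.flanks[1:]):
        parts.append(_tile(unit, length))
        parts.append(flank)
    return "".join(parts)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = lut[lut != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode("ascii")


def simulate_reads(
    config: SimConfig,
    truth: TrueGenotypes,
    outdir,
    gzip_fastq: bool = False,
    per_read_truth: bool = False,
) -> dict:
    """Emit paired FASTQ, the scheme TSV and truth tables for a run.

    Returns a dict of output paths plus per-bin depth bookkeeping.  The
    read-level truth table (read id, haplotype, per-array allele after
    stutter) is optional since it grows with total depth.
    """
    rng = np.random.default_rng(config.seed + 1)  # independent of genotype draw
    os.makedirs(outdir, exist_ok=True)
    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    r1_path = os.path.join(outdir, "r1" + suffix)
    r2_path = os.path.join(outdir, "r2" + suffix)
    opener = gzip.open if gzip_fastq else open
    scheme_path = os.path.join(outdir, "scheme.tsv")
    write_scheme(config.scheme, scheme_path)
    truth_path = os.path.join(outdir, "truth_genotypes.tsv")
    truth.to_table().to_csv(truth_path, sep="\t", index=False)
    samples = {
        s.sample: s for s in config.scheme.samples[: config.n_samples]
    }
    p_loss = config.stutter_loss_ratio / (config.stutter_loss_ratio + 1.0)
    nb_shape = config.depth_dispersion
    nb_p = nb_shape / (nb_shape + config.depth_mean)
    read_rows = []
    n_pairs = 0
    with opener(r1_path, "wt") as f1, opener(r2_path, "wt") as f2:
        for locus in config.loci:
            for sample_name, entry in samples.items():
                h1, h2 = truth.haplotypes[(sample_name, locus.name)]
                depth = int(rng.negative_binomial(nb_shape, nb_p))
                prefix = entry.protective + entry.index + config.scheme.m13
                for r in range(depth):
                    hap_idx = int(rng.integers(2))
                    hap = (h1, h2)[hap_idx]
                    lengths = []
                    stuttered = []
                    for unit, true_len in zip(locus.motifs, hap):
                        length = true_len
                        if config.stutter_prob > 0 and rng.random() < config.stutter_prob:
                            step = len(unit)
                            length += -step if rng.random() < p_loss else step
                            stuttered.append(True)
                        else:
                            stuttered.append(False)
                        lengths.append(length)
                    insert = _build_insert(locus, lengths)
                    construct = (
                        prefix
                        + locus.fwd_primer
                        + insert
                        + revcomp(locus.rev_primer)
                        + revcomp(prefix)
                    )
                    read1 = construct[: config.read_len]
                    read2 = revcomp(construct)[: config.read_len]
                    read1 = _apply_errors(rng, read1, config.error_rate)
                    read2 = _apply_errors(rng, read2, config.error_rate)
                    rid = f"{sample_name}_{locus.name}_{r:06d}"
                    f1.write(f"@{rid}\n{read1}\n+\n{_QUAL_CHAR * len(read1)}\n")
                    f2.write(f"@{rid}\n{read2}\n+\n{_QUAL_CHAR * len(read2)}\n")
                    n_pairs += 1
                    if per_read_truth:
                        read_rows.append(
                            {
                                "read_id": rid,
                                "sample": sample_name,
                                "locus": locus.name,
                                "haplotype": hap_idx,
                                "array_lengths": ";".join(map(str, lengths)),
                                "stuttered": ";".join(
                                    "1" if s else "0" for s in stuttered
                                ),
                            }
                        )
    out = {
        "r1": r1_path,
        "r2": r2_path,
        "scheme": scheme_path,
        "truth": truth_path,
        "n_pairs": n_pairs,
    }
    if per_read_truth:
        import pandas as pd

        rt_path = os.path.join(outdir, "truth_reads.tsv")
        pd.DataFrame(read_rows).to_csv(rt_path, sep="\t", index=False)
        out["truth_reads"] = rt_path
    return out


def expected_canonical_motifs(config: SimConfig) -> dict[str, list[str]]:
    """Canonical motif per simulated array locus (for bookkeeping checks)."""
    out = {}
    for locus in config.loci:
        for name, unit in zip(locus.array_locus_names(), locus.motifs):
            out[name] = [canonical_motif(unit)]
    return out
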