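"""Overlap-based merging of paired-end amplicon mates.

Amplicon inserts are short relative to the read length, so the two
mates of a pair overlap — usually over their full length once primers
are trimmed.  The merger reverse-complements mate 2, scores every
candidate overlap length by (matches - mismatches), and accepts the
best-scoring overlap when its mismatch fraction is within tolerance.
Disagreeing positions take the base with the higher Phred quality
(ties go to mate 1) with consensus quality |q1 - q2|; agreeing
positions keep the higher of the two qualities.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from ._util import ReadRecord, read_fastq, revcomp

DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_FRAC = 0.25


@dataclass(frozen=True)
class MergedRead:
    id: str
    seq: str
    qual: str
    overlap_len: int
    status: str  # merged | unmerged

    @property
    def merged(self) -> bool:
        return self.status == "merged"


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def merge_pair(
    r1: ReadRecord,
    r2: ReadRecord,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> MergedRead:
    """Merge one read pair into a single amplicon sequence.

    Mate 2 is reverse-complemented, then the overlap length ``o`` in
    ``[min_overlap, min(len1, len2)]`` maximising matches - mismatches
    between the suffix of mate 1 and the prefix of the flipped mate 2 is
    selected (ties resolved toward the longer overlap).  The merge is
    rejected (status ``unmerged``) when no candidate overlap keeps its
    mismatch fraction <= ``max_mismatch_frac``.
    """
    len1, len2 = len(r1.seq), len(r2.seq)
    if min(len1, len2) < min_overlap:
        return MergedRead(r1.id, "", "", 0, "unmerged")
    seq2 = revcomp(r2.seq)
    qual2 = r2.qual[::-1]
    a, b = _encode(r1.seq), _encode(seq2)
    # match counts for every relative shift s of the flipped mate 2
    # against mate 1, via one correlation per base channel; s >= 0 is
    # the standard geometry (mate 2 starts inside mate 1), s < 0 the
    # staggered read-through geometry (mate 2 starts before the insert)
    matches = np.zeros(len1 + len2 - 1)
    for base in (65, 67, 71, 84):  # A C G T
        matches += np.correlate((a == base).astype(float), (b == base).astype(float), "full")
    shifts = np.arange(-(len2 - 1), len1)
    ov_len = np.minimum(len1, shifts + len2) - np.maximum(0, shifts)
    mm = ov_len - np.rint(matches).astype(int)
    score = ov_len - 2 * mm
    valid = ov_len >= min_overlap
    if not np.any(valid):
        return MergedRead(r1.id, "", "", 0, "unmerged")
    best = np.flatnonzero(valid & (score == score[valid].max()))
    # ties: standard geometry first, then longer overlap, then smaller shift
    best_k = min(best, key=lambda k: (shifts[k] < 0, -ov_len[k], abs(int(shifts[k]))))
    s, o, best_mm = int(shifts[best_k]), int(ov_len[best_k]), int(mm[best_k])
    if best_mm > max_mismatch_frac * o:
        return MergedRead(r1.id, "", "", 0, "unmerged")
    a_lo = max(0, s)
    b_lo = max(0, -s)
    if s < 0:
        # overhangs flanking a staggered overlap are technical
        # read-through sequence and are discarded
        head_seq = head_qual = tail_seq = tail_qual = ""
    else:
        head_seq, head_qual = r1.seq[:s], r1.qual[:s]
        if s + len2 <= len1:  # mate 2 contained in mate 1
            tail_seq, tail_qual = r1.seq[s + len2 :], r1.qual[s + len2 :]
        else:
            tail_seq, tail_qual = seq2[len1 - s :], qual2[len1 - s :]
    ov1_seq, ov1_qual = r1.seq[a_lo : a_lo + o], r1.qual[a_lo : a_lo + o]
    ov2_seq, ov2_qual = seq2[b_lo : b_lo + o], qual2[b_lo : b_lo + o]
    if best_mm == 0:
        cons_seq = ov1_seq
        cons_qual = "".join(max(q1, q2) for q1, q2 in zip(ov1_qual, ov2_qual))
    else:
        cons = []
        consq = []
        for s1, q1, s2, q2 in zip(ov1_seq, ov1_qual, ov2_seq, ov2_qual):
            if s1 == s2:
                cons.append(s1)
                consq.append(max(q1, q2))
            elif ord(q2) > ord(q1):
                cons.append(s2)
                consq.append(chr(abs(ord(q1) - ord(q2)) + 33))
            else:  # tie in quality -> mate 1's base
                cons.append(s1)
                consq.append(chr(abs(ord(q1) - ord(q2)) + 33))
        cons_seq, cons_qual = "".join(cons), "".join(consq)
    return MergedRead(
        r1.id,
        head_seq + cons_seq + tail_seq,
        head_qual + cons_qual + tail_qual,
        o,
        "merged",
    )


def merge_stream(
    fastq1,
    fastq2,
    out_fastq,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> dict:
    """Merge a bin's mate files; returns {'input', 'merged', 'unmerged'}.

    Identical mate pairs are merged once and the result reused — a pure
    optimisation exploiting the high duplication of amplicon bins.
    """
    cache: dict[tuple[str, str, str, str], MergedRead] = {}
    n_in = n_merged = 0
    it1, it2 = read_fastq(fastq1), read_fastq(fastq2)
    with open(out_fastq, "w") as out:
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                break
            if rec1 is None or rec2 is None:
                raise IOError(f"mate files {fastq1} and {fastq2} are out of sync")
            n_in += 1
            key = (rec1.seq, rec1.qual, rec2.seq, rec2.qual)
            merged = cache.get(key)
            if merged is None:
                merged = merge_pair(rec1, rec2, min_overlap, max_mismatch_frac)
                cache[key] = merged
            if merged.merged:
                n_merged += 1
                out.write(f"@{rec1.id}\n{merged.seq}\n+\n{merged.qual}\n")
    return {"input": n_in, "merged": n_merged, "unmerged": n_in - n_merged}


def merge_directory(
    indir,
    outdir,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
):
    """Merge every demultiplexed bin under ``indir``; returns a stats table."""
    import pandas as pd

    from .scheme_demux import iter_bins

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for sample, locus, p1, p2 in iter_bins(indir):
        out = os.path.join(outdir, f"{sample}__{locus}.merged.fastq")
        stats = merge_stream(p1, p2, out, min_overlap, max_mismatch_frac)
        rows.append(
            {
                "sample": sample,
                "locus": locus,
                **stats,
                "merge_rate": stats["merged"] / stats["input"] if stats["input"] else 0.0,
            }
        )
    table = pd.DataFrame(
        rows, columns=["sample", "locus", "input", "merged", "unmerged", "merge_rate"]
    )
    table.to_csv(os.path.join(outdir, "merge_stats.tsv"), sep="\t", index=False)
    return table
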