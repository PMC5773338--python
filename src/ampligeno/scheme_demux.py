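"""Four-primer amplicon scheme parsing and read-pair demultiplexing.

Libraries built with the tailed two-round PCR design yield reads whose
5' end carries a technical prefix: 4 protective bases, a 10-base sample
index, the M13 universal tail, and the locus-specific primer, followed
by the genomic insert.  Both mates carry the construct, one from each
end.  Demultiplexing resolves the sample from the index (offset 4),
resolves the locus from the target primer located after the M13 tail,
trims the technical sequence from both mates, and normalises
orientation so the forward primer leads mate 1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from ._util import DNA_ALPHABET, ReadRecord, open_text, read_fastq, revcomp, write_fastq

# Standard M13(-21) universal forward primer.
DEFAULT_M13 = "TGTAAAACGACGGCCAGT"

PROTECTIVE_LEN = 4
INDEX_LEN = 10

UNASSIGNED = "UNASSIGNED"

#: window (bp) scanned for the locus primer when the M13 anchor fails
PRIMER_SCAN_WINDOW = 45


class SchemeError(ValueError):
    """The primer/index scheme violates a structural invariant."""


@dataclass(frozen=True)
class LocusDef:
    name: str
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        for label, p in (("fwd", self.fwd_primer), ("rev", self.rev_primer)):
            if not 15 <= len(p) <= 30:
                raise SchemeError(
                    f"locus {self.name}: {label} primer must be 15-30 bp, got {len(p)}"
                )
            if not set(p) <= DNA_ALPHABET:
                raise SchemeError(f"locus {self.name}: {label} primer not ACGT")


@dataclass(frozen=True)
class IndexEntry:
    sample: str
    index: str
    protective: str

    def __post_init__(self) -> None:
        if len(self.index) != INDEX_LEN:
            raise SchemeError(
                f"sample {self.sample}: index must be {INDEX_LEN} bp, got {len(self.index)}"
            )
        if len(self.protective) != PROTECTIVE_LEN:
            raise SchemeError(
                f"sample {self.sample}: protective bases must be {PROTECTIVE_LEN} bp"
            )
        if not set(self.index) <= DNA_ALPHABET or not set(self.protective) <= DNA_ALPHABET:
            raise SchemeError(f"sample {self.sample}: non-ACGT index/protective bases")


@dataclass
class PrimerScheme:
    loci: list[LocusDef]
    samples: list[IndexEntry]
    m13: str = DEFAULT_M13

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SchemeError(f"duplicate locus names: {dup}")
        snames = [s.sample for s in self.samples]
        if len(set(snames)) != len(snames):
            dup = sorted({n for n in snames if snames.count(n) > 1})
            raise SchemeError(f"duplicate sample names: {dup}")
        by_index: dict[str, str] = {}
        for s in self.samples:
            if s.index in by_index:
                raise SchemeError(
                    f"duplicate index {s.index} shared by samples "
                    f"{by_index[s.index]} and {s.sample}"
                )
            by_index[s.index] = s.sample
        for orient in ("fwd_primer", "rev_primer"):
            primers = sorted((getattr(l, orient), l.name) for l in self.loci)
            for (p1, n1), (p2, n2) in zip(primers, primers[1:]):
                if p2.startswith(p1):
                    raise SchemeError(
                        f"{orient} of locus {n1} is a prefix of locus {n2}'s"
                    )

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def sample_names(self) -> list[str]:
        return [s.sample for s in self.samples]


def load_scheme(path) -> PrimerScheme:
    """Load a scheme TSV.

    Rows are tagged by a leading keyword column::

        m13     TGTAAAACGACGGCCAGT
        locus   <name>  <fwd_primer>  <rev_primer>
        sample  <name>  <index10>     <protective4>

    Lines starting with ``#`` and blank lines are ignored.  Violations
    are reported with the offending row number.
    """
    loci: list[LocusDef] = []
    samples: list[IndexEntry] = []
    m13 = DEFAULT_M13
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0].lower()
            try:
                if kind == "m13":
                    m13 = fields[1].upper()
                elif kind == "locus":
                    loci.append(LocusDef(fields[1], fields[2].upper(), fields[3].upper()))
                elif kind == "sample":
                    samples.append(
                        IndexEntry(fields[1], fields[2].upper(), fields[3].upper())
                    )
                else:
                    raise SchemeError(f"unknown record type {fields[0]!r}")
            except (IndexError, SchemeError) as exc:
                raise SchemeError(f"{path} line {lineno}: {exc}") from exc
    return PrimerScheme(loci=loci, samples=samples, m13=m13)


def write_scheme(scheme: PrimerScheme, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"m13\t{scheme.m13}\n")
        for l in scheme.loci:
            fh.write(f"locus\t{l.name}\t{l.fwd_primer}\t{l.rev_primer}\n")
        for s in scheme.samples:
            fh.write(f"sample\t{s.sample}\t{s.index}\t{s.protective}\n")


def _hamming_within(a: str, b: str, limit: int) -> int:
    """Hamming distance of equal-length strings, or limit+1 once exceeded."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def match_prefix(
    seq: str, candidates: Sequence[tuple[str, str]], max_mismatch: int
) -> tuple[str | None, str]:
    """Match the prefix of ``seq`` against candidate patterns.

    Returns ``(name, "ok")`` for the unique candidate at minimal Hamming
    distance <= max_mismatch, ``(None, "none")`` when nothing matches,
    and ``(None, "ambiguous")`` when two or more candidates tie at the
    minimal distance.
    """
    best: str | None = None
    best_d = max_mismatch + 1
    tied = False
    for name, pattern in candidates:
        if len(seq) < len(pattern):
            continue
        d = _hamming_within(seq[: len(pattern)], pattern, max_mismatch)
        if d < best_d:
            best, best_d, tied = name, d, False
        elif d == best_d and d <= max_mismatch:
            tied = True
    if best is None or best_d > max_mismatch:
        return None, "none"
    if tied:
        return None, "ambiguous"
    return best, "ok"


def _find_approx(seq: str, pattern: str, max_mm: int, window: int) -> int:
    """Leftmost offset (< window) where pattern matches within max_mm; -1 if none."""
    pos = seq.find(pattern, 0, window + len(pattern))
    if pos != -1:
        return pos
    plen = len(pattern)
    stop = min(window, len(seq) - plen)
    for off in range(stop + 1):
        if _hamming_within(seq[off : off + plen], pattern, max_mm) <= max_mm:
            return off
    return -1


@dataclass
class DemuxResult:
    sample: str
    locus: str
    r1: ReadRecord | None
    r2: ReadRecord | None
    reason: str  # ok | no_index | no_primer | ambiguous

    @property
    def ok(self) -> bool:
        return self.reason == "ok"


@dataclass
class _Demuxer:
    """Stateful demultiplexer with a classification cache on read prefixes."""

    scheme: PrimerScheme
    index_mm: int = 1
    primer_mm: int = 2
    m13_mm: int = 2
    _index_candidates: list[tuple[str, str]] = field(init=False)
    _cache: dict = field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._index_candidates = [(s.sample, s.index) for s in self.scheme.samples]
        self._prefix_keylen = (
            PROTECTIVE_LEN
            + INDEX_LEN
            + len(self.scheme.m13)
            + max(
                max(len(l.fwd_primer), len(l.rev_primer)) for l in self.scheme.loci
            )
        )

    def _resolve_sample(self, r1: ReadRecord, r2: ReadRecord) -> tuple[str | None, str]:
        seq = r1.seq[PROTECTIVE_LEN:]
        name, status = match_prefix(seq, self._index_candidates, self.index_mm)
        if status == "none":
            # both mates carry the construct; fall back to mate 2
            name, status = match_prefix(
                r2.seq[PROTECTIVE_LEN:], self._index_candidates, self.index_mm
            )
        return name, status

    def _locate_primer(self, seq: str, orient: str) -> tuple[str | None, int, str]:
        """Find a locus primer on one mate.

        Returns (locus, insert_start, status).  The M13 tail anchors the
        primer start; if the tail cannot be located the first
        PRIMER_SCAN_WINDOW bases are scanned for the primer directly.
        """
        m13 = self.scheme.m13
        anchor = PROTECTIVE_LEN + INDEX_LEN
        candidates = [
            (l.name, getattr(l, orient + "_primer")) for l in self.scheme.loci
        ]
        if (
            len(seq) >= anchor + len(m13)
            and _hamming_within(seq[anchor : anchor + len(m13)], m13, self.m13_mm)
            <= self.m13_mm
        ):
            start = anchor + len(m13)
            name, status = match_prefix(seq[start:], candidates, self.primer_mm)
            if status == "ok":
                plen = len(dict(candidates)[name])
                return name, start + plen, "ok"
            if status == "ambiguous":
                return None, -1, "ambiguous"
        # fallback: scan for any locus primer near the read start
        hits = []
        for name, pattern in candidates:
            off = _find_approx(seq, pattern, self.primer_mm, PRIMER_SCAN_WINDOW)
            if off != -1:
                hits.append((off, name, off + len(pattern)))
        if not hits:
            return None, -1, "none"
        hits.sort()
        if len(hits) > 1 and hits[0][0] == hits[1][0]:
            return None, -1, "ambiguous"
        return hits[0][1], hits[0][2], "ok"

    def _classify(self, r1: ReadRecord, r2: ReadRecord):
        """(sample, locus, trim1, trim2, swapped, reason) for a read pair."""
        key = (r1.seq[: self._prefix_keylen], r2.seq[: self._prefix_keylen])
        hit = self._cache.get(key)
        if hit is None:
            hit = self._classify_uncached(r1, r2)
            self._cache[key] = hit
        return hit

    def _classify_uncached(self, r1: ReadRecord, r2: ReadRecord):
        sample, status = self._resolve_sample(r1, r2)
        if status != "ok":
            reason = "no_index" if status == "none" else "ambiguous"
            return None, None, 0, 0, False, reason
        # orientation: forward primer expected on mate 1; otherwise the
        # pair is flipped and mates are swapped after classification
        locus, ins1, st1 = self._locate_primer(r1.seq, "fwd")
        swapped = False
        if st1 != "ok":
            locus, ins1, st1 = self._locate_primer(r2.seq, "fwd")
            swapped = st1 == "ok"
        if st1 != "ok":
            return None, None, 0, 0, False, (
                "ambiguous" if st1 == "ambiguous" else "no_primer"
            )
        other = r1 if swapped else r2
        locus2, ins2, st2 = self._locate_primer(other.seq, "rev")
        if st2 != "ok" or locus2 != locus:
            return None, None, 0, 0, False, (
                "ambiguous" if st2 == "ambiguous" else "no_primer"
            )
        return sample, locus, ins1, ins2, swapped, "ok"

    def __call__(self, r1: ReadRecord, r2: ReadRecord) -> DemuxResult:
        sample, locus, ins1, ins2, swapped, reason = self._classify(r1, r2)
        if reason != "ok":
            return DemuxResult(UNASSIGNED, UNASSIGNED, r1, r2, reason)
        if swapped:
            r1, r2 = r2, r1
        locus_def = next(l for l in self.scheme.loci if l.name == locus)
        t1 = self._trim(r1, ins1, revcomp(locus_def.rev_primer))
        t2 = self._trim(r2, ins2, revcomp(locus_def.fwd_primer))
        return DemuxResult(sample, locus, t1, t2, "ok")

    def _trim(self, read: ReadRecord, insert_start: int, tail_anchor: str) -> ReadRecord:
        """Cut the technical prefix and any read-through past the far primer."""
        seq = read.seq[insert_start:]
        qual = read.qual[insert_start:]
        pos = seq.find(tail_anchor)
        if pos == -1:
            plen = len(tail_anchor)
            for off in range(max(0, len(seq) - plen) + 1):
                if (
                    _hamming_within(seq[off : off + plen], tail_anchor, self.primer_mm)
                    <= self.primer_mm
                ):
                    pos = off
                    break
        if pos != -1:
            seq, qual = seq[:pos], qual[:pos]
        return ReadRecord(read.id, seq, qual)


def demultiplex_read_pair(
    r1: ReadRecord,
    r2: ReadRecord,
    scheme: PrimerScheme,
    index_mm: int = 1,
    primer_mm: int = 2,
) -> DemuxResult:
    """Assign a single read pair to its (sample, locus) bin and trim it."""
    return _Demuxer(scheme, index_mm=index_mm, primer_mm=primer_mm)(r1, r2)


def demux_stream(
    fastq1,
    fastq2,
    scheme: PrimerScheme,
    outdir,
    index_mm: int = 1,
    primer_mm: int = 2,
) -> pd.DataFrame:
    """Demultiplex a FASTQ pair into per-(sample, locus) bin files.

    Bin files are written as ``<sample>__<locus>.R1.fastq`` /
    ``.R2.fastq`` under ``outdir`` plus ``unassigned.R1/.R2.fastq``; the
    returned counts table has one row per (sample, locus) bin and one
    row per unassigned reason, and always partitions the input
    (sum of ``pairs`` equals the number of input pairs).
    """
    os.makedirs(outdir, exist_ok=True)
    demux = _Demuxer(scheme, index_mm=index_mm, primer_mm=primer_mm)
    bins: dict[tuple[str, str], list[tuple[ReadRecord, ReadRecord]]] = {}
    unassigned: list[tuple[ReadRecord, ReadRecord]] = []
    reasons: dict[str, int] = {}
    it1, it2 = read_fastq(fastq1), read_fastq(fastq2)
    n_pairs = 0
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        if rec1 is None and rec2 is None:
            break
        if rec1 is None or rec2 is None:
            raise IOError(f"mate files {fastq1} and {fastq2} have unequal record counts")
        n_pairs += 1
        res = demux(rec1, rec2)
        if res.ok:
            bins.setdefault((res.sample, res.locus), []).append((res.r1, res.r2))
        else:
            unassigned.append((rec1, rec2))
            reasons[res.reason] = reasons.get(res.reason, 0) + 1
    rows = []
    for (sample, locus), pairs in sorted(bins.items()):
        base = os.path.join(outdir, f"{sample}__{locus}")
        with open(base + ".R1.fastq", "w") as f1, open(base + ".R2.fastq", "w") as f2:
            write_fastq((p[0] for p in pairs), f1)
            write_fastq((p[1] for p in pairs), f2)
        rows.append({"sample": sample, "locus": locus, "reason": "ok", "pairs": len(pairs)})
    with open(os.path.join(outdir, "unassigned.R1.fastq"), "w") as f1, open(
        os.path.join(outdir, "unassigned.R2.fastq"), "w"
    ) as f2:
        write_fastq((p[0] for p in unassigned), f1)
        write_fastq((p[1] for p in unassigned), f2)
    for reason, count in sorted(reasons.items()):
        rows.append(
            {"sample": UNASSIGNED, "locus": UNASSIGNED, "reason": reason, "pairs": count}
        )
    counts = pd.DataFrame(rows, columns=["sample", "locus", "reason", "pairs"])
    assert counts["pairs"].sum() == n_pairs if rows else n_pairs == 0
    counts.to_csv(os.path.join(outdir, "demux_counts.tsv"), sep="\t", index=False)
    return counts


def counts_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Pivot the demux counts into a sample x locus depth matrix."""
    ok = counts[counts["reason"] == "ok"]
    if ok.empty:
        return pd.DataFrame()
    return ok.pivot_table(
        index="sample", columns="locus", values="pairs", fill_value=0, aggfunc="sum"
    )


def iter_bins(outdir) -> Iterable[tuple[str, str, str, str]]:
    """Yield (sample, locus, r1_path, r2_path) for every bin in a demux dir."""
    for name in sorted(os.listdir(outdir)):
        if name.endswith(".R1.fastq") and "__" in name:
            sample, locus = name[: -len(".R1.fastq")].split("__", 1)
            yield (
                sample,
                locus,
                os.path.join(outdir, name),
                os.path.join(outdir, name.replace(".R1.", ".R2.")),
            )
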