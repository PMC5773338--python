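"""Detection of microsatellite repeat arrays with a scored tandem scan.

The scanner follows the classic seed-and-extend scheme used by
Sputnik-family SSR finders: every position of the sequence seeds a
candidate repeat unit of each requested size, the candidate is extended
base by base against a perfect tandem continuation of that unit
(match +1, mismatch -6 by default), and the extension that maximises the
cumulative score defines the candidate array.  Candidates must reach a
minimum score, repeat count and purity; overlapping candidates are then
resolved deterministically (higher score, then longer, then leftmost),
yielding maximal non-overlapping arrays.

Alleles downstream are expressed as the length of the repeat array in
base pairs, so coordinates here are 0-based half-open and ``length_bp``
is always ``end - start``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._util import DNA_ALPHABET, revcomp

DEFAULT_UNIT_SIZES = frozenset({2, 3, 4, 5})
DEFAULT_MIN_REPEATS = 6
DEFAULT_MIN_PURITY = 0.9


class InvalidAlphabetError(ValueError):
    """A motif or sequence contains characters outside ACGT(N)."""


class InvalidMotifError(ValueError):
    """A motif unit is empty, out of the 2-6 bp range, or non-primitive."""


@dataclass(frozen=True)
class ScanScoring:
    """Extension scoring for the tandem scan.

    match_score / mismatch_penalty follow the Sputnik convention
    (+1 / -6); ``min_score`` is the score floor for reporting an array;
    ``max_drop`` terminates an extension once the running score has
    fallen that far below its maximum (the array cannot recover purity
    after such a drop at the default thresholds).
    """

    match_score: int = 1
    mismatch_penalty: int = 6
    min_score: int = 8
    max_drop: int = 30


def is_primitive(unit: str) -> bool:
    """True iff ``unit`` is not a tandem repetition of a shorter string."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def canonical_motif(unit: str) -> str:
    """Canonical form of a repeat unit.

    The canonical motif is the lexicographically smallest string over all
    rotations of the unit and all rotations of its reverse complement, so
    e.g. CA, AC, TG and GT all canonicalise to AC.  This is the identity
    under which repeat types are tallied, since the strand and phase of
    an array are arbitrary.
    """
    if not 2 <= len(unit) <= 6:
        raise InvalidMotifError(f"unit length must be 2-6, got {unit!r}")
    if not set(unit) <= DNA_ALPHABET:
        raise InvalidAlphabetError(f"unit must be uppercase ACGT, got {unit!r}")
    if not is_primitive(unit):
        raise InvalidMotifError(f"unit {unit!r} is a repetition of a shorter unit")
    rc = revcomp(unit)
    k = len(unit)
    rotations = [unit[i:] + unit[:i] for i in range(k)]
    rotations += [rc[i:] + rc[:i] for i in range(k)]
    return min(rotations)


@dataclass(frozen=True)
class Motif:
    """A primitive repeat unit together with its canonical form."""

    unit: str
    canonical: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "canonical", canonical_motif(self.unit))


@dataclass(frozen=True)
class RepeatArray:
    """A detected tandem repeat array (the unit of allele definition)."""

    seq_id: str
    motif: Motif
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    length_bp: int
    repeat_count: float
    purity: float
    score: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.length_bp != self.end - self.start:
            raise ValueError("length_bp must equal end - start")


def _extend_seed(
    seq: str, i: int, unit: str, scoring: ScanScoring
) -> tuple[int, int, int]:
    """Best-scoring extension of the seed unit at position ``i``.

    Returns ``(end, score, mismatches)`` for the prefix of the extension
    maximising the cumulative score (ties resolved toward the longer
    array).  The defining unit itself contributes no score.  An N always
    terminates the extension; the running score terminates it once it
    drops ``max_drop`` below the best seen.
    """
    k = len(unit)
    best_end, best_score, best_mm = i + k, 0, 0
    score = 0
    mm = 0
    j = i + k
    n = len(seq)
    while j < n:
        base = seq[j]
        if base == unit[(j - i) % k]:
            score += scoring.match_score
        elif base in DNA_ALPHABET:
            score -= scoring.mismatch_penalty
            mm += 1
        else:  # N or other ambiguity code: hard stop, never inside an array
            break
        j += 1
        if score > best_score or (score == best_score and j > best_end):
            best_end, best_score, best_mm = j, score, mm
        if score < best_score - scoring.max_drop:
            break
    return best_end, best_score, best_mm


def _candidates(
    seq: str,
    unit_sizes: Iterable[int],
    min_repeats: float,
    min_purity: float,
    scoring: ScanScoring,
) -> list[tuple[int, int, str, int, float]]:
    """All threshold-passing candidate arrays as (start, end, unit, score, purity)."""
    out = []
    n = len(seq)
    for k in sorted(set(unit_sizes)):
        for i in range(n - k + 1):
            unit = seq[i : i + k]
            if not set(unit) <= DNA_ALPHABET or not is_primitive(unit):
                continue
            # A seed repeating the previous period yields a strictly
            # dominated sub-array of the seed one period earlier.
            if i >= k and seq[i - k : i] == unit:
                continue
            end, score, mm = _extend_seed(seq, i, unit, scoring)
            length = end - i
            if length < k * min_repeats or score < scoring.min_score:
                continue
            purity = (length - mm) / length
            if purity < min_purity:
                continue
            out.append((i, end, unit, score, purity))
    return out


def resolve_overlaps(
    candidates: Sequence[tuple[int, int, str, int, float]],
) -> list[tuple[int, int, str, int, float]]:
    """Greedy selection of non-overlapping arrays.

    Preference order: higher score, then longer array, then leftmost
    start, then shorter unit, then lexicographic unit (the last two only
    break exact ties deterministically).
    """
    ranked = sorted(
        set(candidates),
        key=lambda c: (-c[3], -(c[1] - c[0]), c[0], len(c[2]), c[2]),
    )
    kept: list[tuple[int, int, str, int, float]] = []
    for cand in ranked:
        if all(cand[1] <= k[0] or cand[0] >= k[1] for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c[0])
    return kept


def find_repeat_arrays(
    sequence: str,
    unit_sizes: Iterable[int] = DEFAULT_UNIT_SIZES,
    min_repeats: float = DEFAULT_MIN_REPEATS,
    min_purity: float = DEFAULT_MIN_PURITY,
    scoring: ScanScoring = ScanScoring(),
    seq_id: str = "",
) -> list[RepeatArray]:
    """Scan one sequence for microsatellite repeat arrays.

    Parameters
    ----------
    sequence
        Uppercase ACGTN nucleotide string; N never falls inside a
        reported array.
    unit_sizes
        Repeat-unit lengths to search (subset of {2, 3, 4, 5, 6}).
    min_repeats
        Minimum repeat count (array length / unit length); default 6.
    min_purity
        Minimum fraction of bases matching a perfect tandem extension of
        the unit; default 0.9.
    scoring
        Extension scoring; see :class:`ScanScoring`.

    Returns
    -------
    list of :class:`RepeatArray`, sorted by start, mutually
    non-overlapping.
    """
    unit_sizes = set(unit_sizes)
    if not unit_sizes <= {2, 3, 4, 5, 6}:
        raise ValueError(f"unit sizes must be within 2-6, got {sorted(unit_sizes)}")
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    if not sequence:
        return []
    kept = resolve_overlaps(
        _candidates(sequence, unit_sizes, min_repeats, min_purity, scoring)
    )
    return [
        RepeatArray(
            seq_id=seq_id,
            motif=Motif(unit),
            start=start,
            end=end,
            length_bp=end - start,
            repeat_count=(end - start) / len(unit),
            purity=purity,
            score=score,
        )
        for start, end, unit, score, purity in kept
    ]


@dataclass
class CatalogSummary:
    """Aggregate statistics over a collection of repeat arrays."""

    n_arrays: int
    raw_unit_counts: Counter
    canonical_unit_counts: Counter
    unit_size_counts: Counter
    repeat_count_hist: Counter  # keyed by floor(repeat_count)
    per_sequence_counts: Counter

    @property
    def most_abundant_canonical(self) -> str | None:
        if not self.canonical_unit_counts:
            return None
        return self.canonical_unit_counts.most_common(1)[0][0]


def summarize_ssr_catalog(arrays: Iterable[RepeatArray]) -> CatalogSummary:
    """Tally an SSR catalog by raw unit, canonical unit, size and repeat count.

    Both the raw (as-scanned) and canonical (strand/rotation-unified)
    tallies are reported, since abundance fractions differ between the
    two conventions.
    """
    raw: Counter = Counter()
    canon: Counter = Counter()
    sizes: Counter = Counter()
    hist: Counter = Counter()
    per_seq: Counter = Counter()
    n = 0
    for arr in arrays:
        n += 1
        raw[arr.motif.unit] += 1
        canon[arr.motif.canonical] += 1
        sizes[len(arr.motif.unit)] += 1
        hist[int(arr.repeat_count)] += 1
        per_seq[arr.seq_id] += 1
    return CatalogSummary(n, raw, canon, sizes, hist, per_seq)


def scan_fasta(
    path,
    unit_sizes: Iterable[int] = DEFAULT_UNIT_SIZES,
    min_repeats: float = DEFAULT_MIN_REPEATS,
    min_purity: float = DEFAULT_MIN_PURITY,
    scoring: ScanScoring = ScanScoring(),
) -> list[RepeatArray]:
    """Scan every record of a (possibly gzipped) FASTA file."""
    from Bio import SeqIO

    from ._util import open_text

    arrays: list[RepeatArray] = []
    with open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            arrays.extend(
                find_repeat_arrays(
                    str(rec.seq).upper(),
                    unit_sizes=unit_sizes,
                    min_repeats=min_repeats,
                    min_purity=min_purity,
                    scoring=scoring,
                    seq_id=rec.id,
                )
            )
    return arrays


def arrays_to_table(arrays: Iterable[RepeatArray]):
    """Repeat arrays as a pandas DataFrame (the TSV report schema)."""
    import pandas as pd

    rows = [
        {
            "seq_id": a.seq_id,
            "start": a.start,
            "end": a.end,
            "unit": a.motif.unit,
            "canonical_unit": a.motif.canonical,
            "length_bp": a.length_bp,
            "repeat_count": a.repeat_count,
            "purity": a.purity,
            "score": a.score,
        }
        for a in arrays
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id",
            "start",
            "end",
            "unit",
            "canonical_unit",
            "length_bp",
            "repeat_count",
            "purity",
            "score",
        ],
    )
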