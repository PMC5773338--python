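"""Depth-based microsatellite genotype calling.

Each merged read of a (sample, locus) bin is scanned for repeat arrays;
every expected array of the amplicon is treated as its own locus
(named ``<amplicon>#<ordinal>``) so that indels in the sequence between
arrays, or PCR errors elsewhere in the amplicon, cannot shift the
allele of a neighbouring array.  An allele is simply the repeat-array
length in base pairs.  Per array, read depths keyed by array length
form the allele-depth table from which a deterministic decision cascade
calls the genotype: a minimum total depth, a minimum per-allele depth
fraction, a one-repeat-unit stutter filter, and a heterozygote depth
ratio.  Calls that remain ambiguous (three or more strong lengths) are
left for manual curation, which the curation report supports by listing
the full length:depth spectrum of every call.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .repeat_finder import ScanScoring, canonical_motif, find_repeat_arrays


@dataclass(frozen=True)
class GenotypeRules:
    """Thresholds of the genotype decision cascade (all configurable)."""

    min_total_depth: int = 10
    min_allele_frac: float = 0.05
    het_ratio: float = 0.3
    stutter_gap: int = 1  # repeat units separating a stutter from its source
    stutter_max_frac: float = 0.5


@dataclass
class AlleleDepthTable:
    """Read depth per repeat-array length for one (sample, array-locus)."""

    sample: str
    locus: str  # amplicon name + array ordinal, e.g. Amp01#1
    unit: str  # repeat unit of the array
    depth_by_length: dict[int, int] = field(default_factory=dict)
    unscored: int = 0  # reads lacking the expected array

    @property
    def total_depth(self) -> int:
        return sum(self.depth_by_length.values())

    def spectrum(self) -> str:
        return ",".join(
            f"{l}:{d}" for l, d in sorted(self.depth_by_length.items())
        )


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    locus: str
    allele1: int | None  # bp; allele1 <= allele2 when called
    allele2: int | None
    status: str  # called | missing_low_depth | ambiguous
    depth1: int = 0
    depth2: int = 0
    total_depth: int = 0
    stutter_filtered: tuple[int, ...] = ()

    @property
    def called(self) -> bool:
        return self.status == "called"

    @property
    def heterozygous(self) -> bool:
        return self.called and self.allele1 != self.allele2


def extract_allele_observations(
    reads: Iterable[str],
    sample: str,
    locus: str,
    expected_motifs: Sequence[str],
    min_repeats: float = 6,
    min_purity: float = 0.9,
    scoring: ScanScoring = ScanScoring(),
) -> list[AlleleDepthTable]:
    """Build one allele-depth table per expected repeat array.

    ``expected_motifs`` lists the repeat units of the amplicon's arrays
    in order of appearance; arrays found in each read are matched to
    these ordinals by canonical motif and order.  Reads in which an
    expected array is not found are tallied as unscored for that
    ordinal.
    """
    expected = [canonical_motif(u) for u in expected_motifs]
    unit_sizes = sorted({len(u) for u in expected_motifs})
    tables = [
        AlleleDepthTable(sample=sample, locus=f"{locus}#{i + 1}", unit=unit)
        for i, unit in enumerate(expected_motifs)
    ]
    cache: dict[str, list[int | None]] = {}
    for seq in reads:
        lengths = cache.get(seq)
        if lengths is None:
            arrays = find_repeat_arrays(
                seq,
                unit_sizes=unit_sizes,
                min_repeats=min_repeats,
                min_purity=min_purity,
                scoring=scoring,
            )
            lengths = []
            pos = 0
            for canon in expected:
                hit = None
                while pos < len(arrays):
                    arr = arrays[pos]
                    pos += 1
                    if arr.motif.canonical == canon:
                        hit = arr.length_bp
                        break
                lengths.append(hit)
            cache[seq] = lengths
        for table, length in zip(tables, lengths):
            if length is None:
                table.unscored += 1
            else:
                table.depth_by_length[length] = table.depth_by_length.get(length, 0) + 1
    return tables


def call_genotype(
    table: AlleleDepthTable, rules: GenotypeRules = GenotypeRules()
) -> GenotypeCall:
    """Apply the decision cascade to one allele-depth table.

    Steps, in order: (1) total depth below ``min_total_depth`` gives
    ``missing_low_depth``; (2) lengths below ``min_allele_frac`` of the
    total are discarded; (3) a retained length exactly ``stutter_gap``
    repeat units shorter than a deeper retained length, with depth at
    most ``stutter_max_frac`` of that length's depth, is flagged as PCR
    stutter and discarded; (4) the two deepest survivors define the
    call — heterozygous when the second's depth reaches ``het_ratio``
    of the first's, homozygous otherwise; (5) three or more survivors
    that strong give ``ambiguous``.
    """
    total = table.total_depth
    if total < rules.min_total_depth:
        return GenotypeCall(
            table.sample, table.locus, None, None, "missing_low_depth",
            total_depth=total,
        )
    depths = table.depth_by_length
    floor = rules.min_allele_frac * total
    retained = {l: d for l, d in depths.items() if d >= floor}
    if not retained:  # degenerate many-way split: keep the deepest length
        lmax = max(depths, key=lambda l: (depths[l], l))
        retained = {lmax: depths[lmax]}
    gap_bp = rules.stutter_gap * len(table.unit)
    stutter = []
    for l, d in retained.items():
        src = l + gap_bp
        if src in retained and retained[src] > d and d <= rules.stutter_max_frac * retained[src]:
            stutter.append(l)
    for l in stutter:
        del retained[l]
    survivors = sorted(retained, key=lambda l: (-retained[l], -l))
    l1 = survivors[0]
    strong = [l for l in survivors if retained[l] >= rules.het_ratio * retained[l1]]
    if len(strong) >= 3:
        return GenotypeCall(
            table.sample, table.locus, None, None, "ambiguous",
            total_depth=total, stutter_filtered=tuple(sorted(stutter)),
        )
    if len(survivors) >= 2 and retained[survivors[1]] >= rules.het_ratio * retained[l1]:
        l2 = survivors[1]
    else:
        l2 = l1
    a1, a2 = sorted((l1, l2))
    return GenotypeCall(
        table.sample,
        table.locus,
        a1,
        a2,
        "called",
        depth1=retained[a1],
        depth2=retained[a2],
        total_depth=total,
        stutter_filtered=tuple(sorted(stutter)),
    )


def _read_seqs(fastq_path) -> Iterable[str]:
    from ._util import read_fastq

    for rec in read_fastq(fastq_path):
        yield rec.seq


def genotype_experiment(
    merged_dir,
    locus_motifs: Mapping[str, Sequence[str]],
    rules: GenotypeRules = GenotypeRules(),
    min_repeats: float = 6,
    min_purity: float = 0.9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype every merged bin under ``merged_dir``.

    ``locus_motifs`` maps each amplicon name to the ordered repeat units
    of its expected arrays.  Returns ``(matrix, report)``: the genotype
    matrix (one row per sample and per-array locus) and the curation
    report carrying the full length:depth spectrum behind every call so
    a curator can override it.
    """
    matrix_rows = []
    report_rows = []
    for name in sorted(os.listdir(merged_dir)):
        if not name.endswith(".merged.fastq"):
            continue
        sample, locus = name[: -len(".merged.fastq")].split("__", 1)
        if locus not in locus_motifs:
            continue
        tables = extract_allele_observations(
            _read_seqs(os.path.join(merged_dir, name)),
            sample,
            locus,
            locus_motifs[locus],
            min_repeats=min_repeats,
            min_purity=min_purity,
        )
        for table in tables:
            call = call_genotype(table, rules)
            matrix_rows.append(
                {
                    "sample": call.sample,
                    "locus": call.locus,
                    "allele1": call.allele1,
                    "allele2": call.allele2,
                    "status": call.status,
                    "depth1": call.depth1,
                    "depth2": call.depth2,
                    "total_depth": call.total_depth,
                }
            )
            report_rows.append(
                {
                    "sample": call.sample,
                    "locus": call.locus,
                    "unit": table.unit,
                    "status": call.status,
                    "allele1": call.allele1,
                    "allele2": call.allele2,
                    "stutter_filtered": ",".join(map(str, call.stutter_filtered)),
                    "unscored_reads": table.unscored,
                    "spectrum": table.spectrum(),
                }
            )
    cols = ["sample", "locus", "allele1", "allele2", "status", "depth1", "depth2", "total_depth"]
    rep_cols = [
        "sample", "locus", "unit", "status", "allele1", "allele2",
        "stutter_filtered", "unscored_reads", "spectrum",
    ]
    return (
        pd.DataFrame(matrix_rows, columns=cols),
        pd.DataFrame(report_rows, columns=rep_cols),
    )


def apply_overrides(
    matrix: pd.DataFrame, report: pd.DataFrame, edits: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Apply manual curation edits to a genotype matrix.

    ``edits`` columns: sample, locus, allele1, allele2.  An edit naming
    an allele length absent from the call's depth spectrum is rejected.
    Returns the updated matrix and a log of applied/rejected edits.
    """
    matrix = matrix.copy()
    spectra = {
        (r.sample, r.locus): dict(
            (int(p.split(":")[0]), int(p.split(":")[1]))
            for p in str(r.spectrum).split(",")
            if ":" in p
        )
        for r in report.itertuples()
    }
    log = []
    for e in edits.itertuples():
        key = (e.sample, e.locus)
        spectrum = spectra.get(key)
        if spectrum is None:
            log.append(f"REJECTED {key}: no such call")
            continue
        a1, a2 = sorted((int(e.allele1), int(e.allele2)))
        missing = [a for a in {a1, a2} if a not in spectrum]
        if missing:
            log.append(
                f"REJECTED {key}: allele(s) {missing} absent from depth spectrum"
            )
            continue
        mask = (matrix["sample"] == e.sample) & (matrix["locus"] == e.locus)
        matrix.loc[mask, ["allele1", "allele2", "status"]] = [a1, a2, "called"]
        matrix.loc[mask, "depth1"] = spectrum[a1]
        matrix.loc[mask, "depth2"] = spectrum[a2]
        log.append(f"APPLIED {key}: ({a1}, {a2})")
    return matrix, log
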