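"""Shared low-level helpers: sequence ops and FASTQ I/O."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import IO, Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read: identifier, bases, Phred+33 quality string."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual]


def open_text(path, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Iterate FASTQ records (Phred+33; plain or gzipped)."""
    with open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"{path}: malformed FASTQ header {header!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ separator near {header!r}")
            yield ReadRecord(id=header[1:].split()[0], seq=seq, qual=qual)


def write_fastq(records, handle: IO[str]) -> int:
    """Write records to an open text handle; returns the record count."""
    n = 0
    for rec in records:
        handle.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
        n += 1
    return n
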