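"""FASTQ / FASTA / report input-output.

Reads are plain Phred+33 FASTQ, optionally gzipped (detected by the ``.gz``
suffix).  Mate identity (R1/R2) comes from which file a record was read from,
never from header parsing.  References are FASTA; soft-masked (lower-case)
bases are uppercased on load and sequence names are the first
whitespace-delimited header token.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._codec import qual_to_string, seq_to_codes, string_to_qual

__all__ = [
    "ReadRecord",
    "ReferenceSet",
    "FastqFormatError",
    "ReferenceError_",
    "read_fastq",
    "read_fastq_pairs",
    "write_fastq",
    "read_reference",
    "write_fasta",
    "write_json",
]


class FastqFormatError(ValueError):
    """Malformed FASTQ record (carries the offending record id)."""


class ReferenceError_(ValueError):
    """Problem with a reference FASTA or a missing reference sequence."""


@dataclass(eq=False)
class ReadRecord:
    """A single sequencing read with per-base Phred qualities.

    ``mate`` is ``"R1"``/``"R2"`` for paired input and ``"merged"`` for reads
    produced by overlap merging.
    """

    id: str
    seq: str
    qual: np.ndarray  # integer Phred scores, same length as seq
    mate: str = "R1"

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.int16)
        if len(self.seq) != len(self.qual):
            raise FastqFormatError(
                f"record {self.id!r}: sequence length {len(self.seq)} "
                f"!= quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadRecord):
            return NotImplemented
        return (
            self.id == other.id
            and self.seq == other.seq
            and self.mate == other.mate
            and np.array_equal(self.qual, other.qual)
        )

    @property
    def codes(self) -> np.ndarray:
        return seq_to_codes(self.seq)

    def trimmed(self, left: int, right: int) -> "ReadRecord":
        end = len(self.seq) - right
        return ReadRecord(self.id, self.seq[left:end], self.qual[left:end], self.mate)


def _xopen(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # fixed mtime so identical content gives identical bytes
            import io as _io

            gz = gzip.GzipFile(
                filename="", fileobj=open(path, "wb"), mode="wb", mtime=0
            )
            return _io.TextIOWrapper(gz) if "t" in mode or "b" not in mode else gz
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, mate: str = "R1") -> Iterator[ReadRecord]:
    """Stream ReadRecords from a (possibly gzipped) Phred+33 FASTQ file."""
    with _xopen(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            rid = title.split()[0] if title else ""
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"record {rid!r}: sequence/quality length mismatch"
                )
            try:
                seq_to_codes(seq)
            except ValueError as exc:
                raise FastqFormatError(f"record {rid!r}: {exc}") from exc
            yield ReadRecord(rid, seq.upper(), string_to_qual(qual), mate)


def read_fastq_pairs(
    path1: str | Path, path2: str | Path
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Stream mate pairs from parallel R1/R2 FASTQ files."""
    it1 = read_fastq(path1, "R1")
    it2 = read_fastq(path2, "R2")
    for r1, r2 in zip(it1, it2, strict=True):
        yield r1, r2


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Write records as Phred+33 FASTQ; round-trips byte-identically."""
    with _xopen(path, "wt") as out:
        for rec in records:
            out.write(f"@{rec.id}\n{rec.seq}\n+\n{qual_to_string(rec.qual)}\n")


class ReferenceSet:
    """Named reference sequences with exact-slice lookup.

    Sequences are stored uppercased; ``fetch`` uses 0-based half-open
    intervals.  ``codes`` returns (and caches) the uint8 encoding used by the
    vectorised mismatch machinery.
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ReferenceError_("reference set is empty")
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}
        self._codes: dict[str, np.ndarray] = {}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSet":
        seqs: dict[str, str] = {}
        with _xopen(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                name = rec.id
                if name in seqs:
                    raise ReferenceError_(f"duplicate reference name {name!r}")
                seqs[name] = str(rec.seq)
        if not seqs:
            raise ReferenceError_(f"no sequences in {path}")
        return cls(seqs)

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        try:
            return self._seqs[name]
        except KeyError:
            raise ReferenceError_(f"unknown reference sequence {name!r}") from None

    def length(self, name: str) -> int:
        return len(self[name])

    def fetch(self, name: str, start: int, end: int) -> str:
        return self[name][start:end]

    def codes(self, name: str) -> np.ndarray:
        if name not in self._codes:
            self._codes[name] = seq_to_codes(self[name], strict=False)
        return self._codes[name]

    def items(self):
        return self._seqs.items()


def read_reference(path: str | Path) -> ReferenceSet:
    return ReferenceSet.from_fasta(path)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _xopen(path, "wt") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as out:
        json.dump(obj, out, indent=2, sort_keys=True)
        out.write("\n")
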