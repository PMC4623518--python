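"""Hard trimming and read-cleanup stages.

These are the pre-alignment cleanup steps applied to a damaged library once
trim lengths have been decided: fixed-length end trimming, exact-duplicate
removal, mean-quality / N-content filtering, and merging of overlapping
paired-end reads.  Adapter trimming is deliberately not implemented here;
run a standard adapter trimmer (e.g. fastp or cutadapt) upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Optional

import numpy as np

from ._codec import revcomp
from .damage import TrimSpec
from .io import ReadRecord

__all__ = [
    "TrimReport",
    "DuplicationReport",
    "FilterReport",
    "MergeResult",
    "MergeReport",
    "apply_trim",
    "remove_duplicates",
    "quality_filter",
    "merge_overlaps",
    "merge_pairs",
]

Pair = tuple[ReadRecord, ReadRecord]


@dataclass
class TrimReport:
    total_pairs: int
    kept_pairs: int
    dropped_pairs: int

    def to_dict(self) -> dict:
        return {"stage": "trim", **asdict(self)}


@dataclass
class DuplicationReport:
    total_pairs: int
    unique_pairs: int

    @property
    def duplicate_fraction(self) -> float:
        if self.total_pairs == 0:
            return 0.0
        return 1.0 - self.unique_pairs / self.total_pairs

    def to_dict(self) -> dict:
        return {
            "stage": "dedup",
            **asdict(self),
            "duplicate_fraction": self.duplicate_fraction,
        }


@dataclass
class FilterReport:
    total: int
    kept: int
    dropped: int

    def to_dict(self) -> dict:
        return {"stage": "qfilter", **asdict(self)}


@dataclass
class MergeResult:
    """Outcome of overlap merging for one pair: exactly one of ``merged`` /
    ``kept_pair`` is set."""

    merged: Optional[ReadRecord]
    kept_pair: Optional[Pair]
    overlap_len: int = 0
    mismatches_in_overlap: int = 0


@dataclass
class MergeReport:
    total_pairs: int
    merged: int
    kept_pairs: int

    def to_dict(self) -> dict:
        return {"stage": "merge", **asdict(self)}


def apply_trim(
    pairs: Iterable[Pair], spec: TrimSpec, min_len: int = 30
) -> tuple[list[Pair], TrimReport]:
    """Remove fixed numbers of bases from each end of each mate.

    A pair is dropped entirely when either trimmed mate is shorter than
    ``min_len`` (including the case where the trim exceeds the read length).
    """
    kept: list[Pair] = []
    total = 0
    for r1, r2 in pairs:
        total += 1
        if len(r1) - spec.r1_5p - spec.r1_3p < min_len:
            continue
        if len(r2) - spec.r2_5p - spec.r2_3p < min_len:
            continue
        kept.append(
            (r1.trimmed(spec.r1_5p, spec.r1_3p), r2.trimmed(spec.r2_5p, spec.r2_3p))
        )
    return kept, TrimReport(total, len(kept), total - len(kept))


def remove_duplicates(
    pairs: Iterable[Pair],
) -> tuple[list[Pair], DuplicationReport]:
    """Drop exact sequence duplicates, keeping the first occurrence.

    The key is the concatenated R1/R2 sequences; qualities and read names are
    ignored, so the operation is usable before alignment and is deterministic
    for a given input order.
    """
    seen: set[str] = set()
    unique: list[Pair] = []
    total = 0
    for r1, r2 in pairs:
        total += 1
        key = r1.seq + "|" + r2.seq
        if key in seen:
            continue
        seen.add(key)
        unique.append((r1, r2))
    return unique, DuplicationReport(total, len(unique))


def _read_ok(rec: ReadRecord, min_mean_q: float, max_n_frac: float) -> bool:
    if len(rec) == 0:
        return False
    if float(np.mean(rec.qual)) < min_mean_q:
        return False
    n_frac = rec.seq.count("N") / len(rec)
    return n_frac <= max_n_frac


def quality_filter(
    pairs: Iterable[Pair], min_mean_q: float = 20.0, max_n_frac: float = 0.1
) -> tuple[list[Pair], FilterReport]:
    """Drop pairs where either mate has mean Phred < ``min_mean_q`` (>= keeps)
    or an N fraction above ``max_n_frac``."""
    kept = []
    total = 0
    for r1, r2 in pairs:
        total += 1
        if _read_ok(r1, min_mean_q, max_n_frac) and _read_ok(r2, min_mean_q, max_n_frac):
            kept.append((r1, r2))
    return kept, FilterReport(total, len(kept), total - len(kept))


def merge_overlaps(
    r1: ReadRecord,
    r2: ReadRecord,
    min_overlap: int = 11,
    max_mismatch_frac: float = 0.1,
) -> MergeResult:
    """Merge a read pair whose mates overlap.

    R2 is reverse-complemented, candidate overlap lengths are scanned from
    the longest possible down to ``min_overlap``, and the first candidate
    whose mismatch fraction is within ``max_mismatch_frac`` is accepted.
    Within the overlap each column takes the higher-quality base (R1 wins
    ties) and the maximum of the two qualities.  With no acceptable overlap
    the original pair is returned unchanged.
    """
    c1 = r1.codes
    rc2_seq = revcomp(r2.seq)
    c2 = ReadRecord(r2.id, rc2_seq, r2.qual[::-1].copy(), r2.mate).codes
    q1, q2 = r1.qual, r2.qual[::-1]
    l1, l2 = len(c1), len(c2)

    for o in range(min(l1, l2), min_overlap - 1, -1):
        a = c1[l1 - o :]
        b = c2[:o]
        mism = int(np.count_nonzero(a != b))
        if mism <= max_mismatch_frac * o:
            qa = q1[l1 - o :]
            qb = q2[:o]
            take_b = qb > qa  # ties -> R1 base
            ov_codes = np.where(take_b, b, a)
            ov_qual = np.maximum(qa, qb)
            seq = r1.seq[: l1 - o] + _codes_str(ov_codes) + rc2_seq[o:]
            qual = np.concatenate([q1[: l1 - o], ov_qual, q2[o:]])
            merged = ReadRecord(r1.id, seq, qual, "merged")
            return MergeResult(merged, None, o, mism)
    return MergeResult(None, (r1, r2), 0, 0)


def _codes_str(codes: np.ndarray) -> str:
    from ._codec import codes_to_seq

    return codes_to_seq(codes)


def merge_pairs(
    pairs: Iterable[Pair], min_overlap: int = 11, max_mismatch_frac: float = 0.1
) -> tuple[list[ReadRecord], list[Pair], MergeReport]:
    """Apply :func:`merge_overlaps` to a stream; merged reads are returned
    separately from surviving pairs (downstream treats them as unpaired)."""
    merged: list[ReadRecord] = []
    kept: list[Pair] = []
    total = 0
    for r1, r2 in pairs:
        total += 1
        res = merge_overlaps(r1, r2, min_overlap, max_mismatch_frac)
        if res.merged is not None:
            merged.append(res.merged)
        else:
            kept.append(res.kept_pair)
    return merged, kept, MergeReport(total, len(merged), len(kept))
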