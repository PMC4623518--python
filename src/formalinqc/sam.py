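"""SAM parsing and read-space mismatch extraction.

Alignments are consumed through pysam (plain SAM; BAM works too but is not
required anywhere).  The central primitive is :func:`aligned_columns`, which
walks the CIGAR of one primary alignment and returns, for every comparable
aligned column (M/=/X, both bases non-N), the reference and read base *in
sequenced-read orientation* together with the column's distance from the
read's 5' and 3' ends.

Orientation convention
----------------------
Base-misincorporation damage is an end-of-molecule effect, so profiles are
accumulated in read space: for reverse-strand alignments both bases are
complemented and offsets flipped, making ``offset5`` the distance from the 5'
end of the read *as sequenced*.  Soft-clipped bases are never compared (they
still count toward read length / offsets); hard clips are ignored entirely.
Insertions and deletions contribute no columns but advance the cursors per
SAM semantics.

The reference set is the authoritative source of reference bases.  When an
alignment's reference is absent from the set, the MD tag is used instead; if
both are available and disagree, the reference set wins with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pysam

from ._codec import BASES, COMPLEMENT, seq_to_codes
from .io import ReferenceSet, ReferenceError_

__all__ = [
    "MismatchObservation",
    "Columns",
    "read_alignments",
    "aligned_columns",
    "extract_mismatches",
    "passes_filters",
]

# CIGAR op codes (pysam numeric): M=0, I=1, D=2, N=3, S=4, H=5, P=6, ==7, X=8
_QUERY_CONSUMING = {0, 1, 4, 7, 8}
_REF_CONSUMING = {0, 2, 3, 7, 8}
_MATCH_OPS = {0, 7, 8}


class MismatchObservation(NamedTuple):
    """One reference/read base disagreement in sequenced-read orientation."""

    ref_base: str
    read_base: str
    offset5: int
    offset3: int
    mate: str
    ref_name: str
    ref_pos: int  # 0-based reference coordinate of the column


class Columns(NamedTuple):
    """Comparable aligned columns of one alignment (read-space)."""

    offset5: np.ndarray  # distance from sequenced 5' end
    offset3: np.ndarray  # distance from sequenced 3' end
    ref_codes: np.ndarray  # reference base codes, read-space orientation
    read_codes: np.ndarray  # read base codes, read-space orientation
    ref_pos: np.ndarray  # 0-based reference positions
    read_len: int


def read_alignments(
    path: str | Path, refset: ReferenceSet | None = None
) -> Iterator[pysam.AlignedSegment]:
    """Stream alignment records from a SAM/BAM file.

    All records are yielded, including unmapped/secondary/supplementary ones
    (callers filter with :func:`passes_filters`).  If a reference set is given,
    header sequence names must be covered by it.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        if refset is not None:
            missing = [n for n in fh.references if n not in refset]
            if missing:
                raise ReferenceError_(
                    f"alignment references not in reference set: {missing}"
                )
        yield from fh


def passes_filters(aln: pysam.AlignedSegment, mapq_min: int = 20) -> bool:
    """Default eligibility for profiles and error rates: primary, mapped,
    MAPQ at or above the floor (ambiguous placements inflate apparent
    mismatch rates)."""
    return (
        not aln.is_unmapped
        and not aln.is_secondary
        and not aln.is_supplementary
        and aln.mapping_quality >= mapq_min
    )


def mate_of(aln: pysam.AlignedSegment) -> str:
    if aln.is_paired:
        return "R2" if aln.is_read2 else "R1"
    return "merged"


def _reference_codes(aln: pysam.AlignedSegment, refset: ReferenceSet | None) -> np.ndarray | None:
    """Reference codes spanning the alignment, from the refset when possible,
    else reconstructed from the MD tag."""
    name = aln.reference_name
    if refset is not None and name in refset:
        ref = refset.codes(name)[aln.reference_start : aln.reference_end]
        if aln.has_tag("MD"):
            try:
                md_seq = aln.get_reference_sequence().upper()
                md = seq_to_codes(md_seq, strict=False)
                if len(md) != len(ref) or not np.array_equal(
                    np.where(md == 4, ref, md), ref
                ):
                    warnings.warn(
                        f"MD tag of {aln.query_name!r} disagrees with the "
                        "reference set; using the reference set",
                        stacklevel=2,
                    )
            except (ValueError, AssertionError):
                warnings.warn(
                    f"MD tag of {aln.query_name!r} is inconsistent with its "
                    "CIGAR; using the reference set",
                    stacklevel=2,
                )
        return ref
    if aln.has_tag("MD"):
        return seq_to_codes(aln.get_reference_sequence().upper(), strict=False)
    return None


def aligned_columns(
    aln: pysam.AlignedSegment, refset: ReferenceSet | None
) -> Columns:
    """Walk the CIGAR and return comparable columns in read space.

    Raises :class:`ReferenceError_` when neither the reference set nor an MD
    tag can supply reference bases.
    """
    seq = aln.query_sequence
    if seq is None:
        raise ValueError(f"alignment {aln.query_name!r} has no sequence")
    read = seq_to_codes(seq.upper(), strict=False)
    ref = _reference_codes(aln, refset)
    if ref is None:
        raise ReferenceError_(
            f"no reference bases available for {aln.query_name!r} "
            f"(reference {aln.reference_name!r} missing and no MD tag)"
        )
    read_len = len(read)

    q_parts: list[np.ndarray] = []
    r_parts: list[np.ndarray] = []
    q = 0  # query cursor (includes soft clips)
    r = 0  # cursor into `ref` (alignment-local reference coordinates)
    for op, length in aln.cigartuples or []:
        if op in _MATCH_OPS:
            q_parts.append(np.arange(q, q + length))
            r_parts.append(np.arange(r, r + length))
            q += length
            r += length
        else:
            if op in _QUERY_CONSUMING:
                q += length
            if op in _REF_CONSUMING:
                r += length
    if not q_parts:
        empty = np.empty(0, dtype=np.int64)
        return Columns(empty, empty, empty.astype(np.uint8), empty.astype(np.uint8), empty, read_len)

    q_idx = np.concatenate(q_parts)
    r_idx = np.concatenate(r_parts)
    read_c = read[q_idx]
    ref_c = ref[r_idx]

    # drop non-comparable columns (either base N or unknown)
    ok = (read_c < 4) & (ref_c < 4)
    q_idx, r_idx = q_idx[ok], r_idx[ok]
    read_c, ref_c = read_c[ok], ref_c[ok]

    if aln.is_reverse:
        offset5 = read_len - 1 - q_idx
        read_c = COMPLEMENT[read_c]
        ref_c = COMPLEMENT[ref_c]
    else:
        offset5 = q_idx
    offset3 = read_len - 1 - offset5
    return Columns(
        offset5, offset3, ref_c, read_c, r_idx + aln.reference_start, read_len
    )


def extract_mismatches(
    aln: pysam.AlignedSegment, refset: ReferenceSet | None
) -> tuple[list[MismatchObservation], int]:
    """Mismatch observations of one alignment plus its aligned-base count.

    The aligned-base count is the number of comparable columns (the
    denominator for empirical error rates).
    """
    cols = aligned_columns(aln, refset)
    mate = mate_of(aln)
    mm = cols.ref_codes != cols.read_codes
    obs = [
        MismatchObservation(
            BASES[rc],
            BASES[qc],
            int(o5),
            int(o3),
            mate,
            aln.reference_name,
            int(rp),
        )
        for rc, qc, o5, o3, rp in zip(
            cols.ref_codes[mm],
            cols.read_codes[mm],
            cols.offset5[mm],
            cols.offset3[mm],
            cols.ref_pos[mm],
        )
    ]
    return obs, int(len(cols.offset5))
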