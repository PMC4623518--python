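"""Reference-based summary statistics.

Empirical error rate (mismatched / aligned bases over a region), binned
coverage and genome-wide breadth/depth, pileup construction, majority-rule
consensus calling with SNP counting and sequence dissimilarity, GC content
and contig length filtering with N50.

Only primary, mapped alignments at or above a MAPQ floor contribute, using
the same column semantics as the damage profiles (soft clips and N columns
excluded; insertions ignored; deleted reference positions receive no base
evidence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

from ._codec import BASES, seq_to_codes
from .io import ReferenceSet, write_fasta
from .sam import aligned_columns, passes_filters

__all__ = [
    "ErrorRateResult",
    "CoverageTable",
    "Pileup",
    "ConsensusResult",
    "Snp",
    "UndefinedRateError",
    "error_rate",
    "coverage_bins",
    "build_pileup",
    "call_consensus",
    "gc_content",
    "length_filter",
    "n50",
]


class UndefinedRateError(ZeroDivisionError):
    """A rate was requested over a region with no aligned bases."""


Region = tuple[str, int, int]


def _resolve_region(region: str | Region, refset: ReferenceSet) -> Region:
    if isinstance(region, str):
        return region, 0, refset.length(region)
    name, start, end = region
    ref_len = refset.length(name)
    if not (0 <= start < end <= ref_len):
        raise ValueError(f"region {region} outside reference bounds [0, {ref_len})")
    return name, start, end


def _eligible(sam_path: str | Path, mapq_min: int):
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for aln in fh:
            if passes_filters(aln, mapq_min):
                yield aln


@dataclass
class ErrorRateResult:
    region: Region
    mismatched_bases: int
    aligned_bases: int

    @property
    def rate(self) -> float:
        return self.mismatched_bases / self.aligned_bases


def error_rate(
    sam_path: str | Path,
    refset: ReferenceSet,
    region: str | Region,
    mapq_min: int = 20,
) -> ErrorRateResult:
    """Empirical error rate: mismatched bases / aligned bases in a region."""
    name, start, end = _resolve_region(region, refset)
    mism = 0
    aligned = 0
    for aln in _eligible(sam_path, mapq_min):
        if aln.reference_name != name:
            continue
        cols = aligned_columns(aln, refset)
        in_region = (cols.ref_pos >= start) & (cols.ref_pos < end)
        aligned += int(np.count_nonzero(in_region))
        mism += int(
            np.count_nonzero(in_region & (cols.ref_codes != cols.read_codes))
        )
    if aligned == 0:
        raise UndefinedRateError(f"no aligned bases in region {name}:{start}-{end}")
    return ErrorRateResult((name, start, end), mism, aligned)


@dataclass
class CoverageTable:
    """Binned read counts and depth plus genome-wide summaries.

    ``bins`` columns: ref, start, end, read_count, mean_depth.  A read is
    assigned to exactly one bin by its leftmost aligned base, so bin counts
    sum to the number of counted alignments.  Depth uses the full reference
    span of each alignment (M/=/X/D consume reference).
    """

    bins: pd.DataFrame
    breadth: float
    mean_depth: float
    total_reads: int


def coverage_bins(
    sam_path: str | Path,
    refset: ReferenceSet,
    bin_size: int = 10_000,
    mapq_min: int = 20,
) -> CoverageTable:
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    depth = {name: np.zeros(len(seq) + 1, dtype=np.int64) for name, seq in refset.items()}
    counts = {
        name: np.zeros(-(-len(seq) // bin_size), dtype=np.int64)
        for name, seq in refset.items()
    }
    total_reads = 0
    for aln in _eligible(sam_path, mapq_min):
        name = aln.reference_name
        if name not in depth:
            continue
        s, e = aln.reference_start, aln.reference_end
        diff = depth[name]
        diff[s] += 1
        diff[e] -= 1
        counts[name][s // bin_size] += 1
        total_reads += 1

    rows = []
    covered = 0
    depth_sum = 0
    genome_len = 0
    for name, seq in refset.items():
        per_base = np.cumsum(depth[name][:-1])
        genome_len += len(seq)
        covered += int(np.count_nonzero(per_base))
        depth_sum += int(per_base.sum())
        for b, rc in enumerate(counts[name]):
            s = b * bin_size
            e = min(s + bin_size, len(seq))
            rows.append((name, s, e, int(rc), float(per_base[s:e].mean())))
    bins = pd.DataFrame(rows, columns=["ref", "start", "end", "read_count", "mean_depth"])
    return CoverageTable(
        bins=bins,
        breadth=covered / genome_len,
        mean_depth=depth_sum / genome_len,
        total_reads=total_reads,
    )


@dataclass
class Pileup:
    """Per-position base counts over a region (reference orientation)."""

    region: Region
    counts: np.ndarray  # shape (region length, 4)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def build_pileup(
    sam_path: str | Path,
    refset: ReferenceSet,
    region: str | Region,
    mapq_min: int = 20,
) -> Pileup:
    """Tally aligned read bases per reference position.

    Bases are counted in reference orientation (as stored in the SAM);
    N columns are excluded, deletions contribute nothing at the deleted
    positions, insertions are ignored.
    """
    name, start, end = _resolve_region(region, refset)
    counts = np.zeros((end - start, 4), dtype=np.int64)
    ref_codes_full = refset.codes(name)
    for aln in _eligible(sam_path, mapq_min):
        if aln.reference_name != name:
            continue
        seq = aln.query_sequence
        if seq is None or not aln.cigartuples:
            continue
        read = seq_to_codes(seq.upper(), strict=False)
        q = 0
        r = aln.reference_start
        for op, length in aln.cigartuples:
            if op in (0, 7, 8):  # M/=/X
                lo = max(r, start)
                hi = min(r + length, end)
                if lo < hi:
                    base = read[q + (lo - r) : q + (hi - r)]
                    pos = np.arange(lo - start, hi - start)
                    ok = base < 4
                    np.add.at(counts, (pos[ok], base[ok]), 1)
                q += length
                r += length
            elif op in (1, 4):  # I/S consume query
                q += length
            elif op in (2, 3):  # D/N consume reference
                r += length
            # H/P consume neither
    return Pileup((name, start, end), counts)


class Snp(NamedTuple):
    pos: int  # 0-based reference position
    ref_base: str
    called_base: str
    depth: int
    alt_fraction: float


@dataclass
class ConsensusResult:
    """Majority-rule consensus over a region with SNPs vs the reference."""

    region: Region
    sequence: str
    depth: np.ndarray
    snps: list[Snp]
    called_sites: int

    @property
    def dissimilarity(self) -> float:
        if self.called_sites == 0:
            return 0.0
        return len(self.snps) / self.called_sites

    def to_fasta(self, path: str | Path, name: str | None = None) -> None:
        name = name or f"{self.region[0]}_consensus"
        write_fasta({name: self.sequence}, path)

    def snps_to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [
                (s.pos + 1, s.ref_base, s.called_base, s.depth, round(s.alt_fraction, 4))
                for s in self.snps
            ],
            columns=["pos", "ref", "alt", "depth", "alt_fraction"],
        )
        df.to_csv(path, sep="\t", index=False)


def call_consensus(
    pileup: Pileup,
    refset: ReferenceSet,
    min_depth: int = 3,
    maj_frac: float = 0.75,
) -> ConsensusResult:
    """Call a consensus base per site: the majority base when depth and
    majority fraction suffice, else N.  Ties give N (never the reference
    base, to avoid reference bias in SNP counts).  SNPs and dissimilarity
    are computed over called (non-N) sites only."""
    name, start, end = pileup.region
    counts = pileup.counts
    depth = pileup.depth
    ref_codes = refset.codes(name)[start:end]

    top = counts.argmax(axis=1)
    top_n = counts[np.arange(len(counts)), top]
    # a tie exists when removing the top count still leaves an equal count
    tied = (counts == top_n[:, None]).sum(axis=1) > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, top_n / np.maximum(depth, 1), 0.0)
    called = (depth >= min_depth) & (frac >= maj_frac) & ~tied

    out = np.full(end - start, 4, dtype=np.uint8)
    out[called] = top[called]
    snp_sites = np.nonzero(called & (top != ref_codes) & (ref_codes < 4))[0]
    snps = [
        Snp(
            int(start + i),
            BASES[ref_codes[i]],
            BASES[top[i]],
            int(depth[i]),
            float(top_n[i] / depth[i]),
        )
        for i in snp_sites
    ]
    from ._codec import codes_to_seq

    return ConsensusResult(
        pileup.region,
        codes_to_seq(out),
        depth.copy(),
        snps,
        int(np.count_nonzero(called)),
    )


def gc_content(sequences: str | Iterable[str]) -> float:
    """(G+C) / (A+C+G+T); N bases are excluded from the denominator."""
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = 0
    acgt = 0
    for seq in sequences:
        codes = seq_to_codes(seq.upper(), strict=False)
        counts = np.bincount(codes, minlength=5)
        gc += int(counts[1] + counts[2])
        acgt += int(counts[:4].sum())
    if acgt == 0:
        raise UndefinedRateError("no ACGT bases; GC content undefined")
    return gc / acgt


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L sum to at least half the
    total length.  0 (with a warning) for an empty set."""
    if len(lengths) == 0:
        warnings.warn("N50 of an empty contig set is undefined; reporting 0")
        return 0
    arr = np.sort(np.asarray(lengths))[::-1]
    csum = np.cumsum(arr)
    half = csum[-1] / 2
    return int(arr[np.searchsorted(csum, half)])


def length_filter(
    contigs: dict[str, str] | Sequence[str], min_len: int = 200
) -> tuple[dict[str, str] | list[str], int]:
    """Drop contigs shorter than ``min_len``; return survivors and their N50."""
    if isinstance(contigs, dict):
        kept: dict[str, str] | list[str] = {
            k: v for k, v in contigs.items() if len(v) >= min_len
        }
        lengths = [len(v) for v in kept.values()]
    else:
        kept = [c for c in contigs if len(c) >= min_len]
        lengths = [len(c) for c in kept]
    return kept, n50(lengths)
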