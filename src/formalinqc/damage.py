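"""Mismatch-frequency profiles and data-driven hard-trim detection.

Formalin fixation leaves a signature of base misincorporation concentrated at
the ends of sequenced fragments: when damaged reads are aligned to a
reference, all twelve ref->read substitution types show elevated frequencies
near the 5' and 3' read ends, decaying toward an interior plateau set by the
sequencing error rate.  This module accumulates those per-type,
per-offset frequencies and turns "trim until the ends look like the
interior" into an explicit statistical rule.

Frequency convention
--------------------
For each mate and each read end, ``count[ref][alt][offset]`` is the number of
comparable aligned columns at that offset where the reference base ``ref``
was read as ``alt``; ``denom[ref][offset]`` is the number of comparable
columns at that offset whose reference base is ``ref``.  Frequencies are
``count / denom`` — i.e. each substitution type is normalised by the
occurrences of its own reference base, the convention used by
misincorporation plots in the ancient-DNA literature.  This keeps a type's
baseline at ``error_rate / 3`` regardless of base composition.

Trim detection
--------------
For each of the four (mate, end) combinations independently:

1. per type, a robust baseline is estimated over an interior offset window:
   median ``m_t`` and MAD ``s_t`` of the per-offset frequencies (offsets with
   denominator below ``min_denom`` are ignored);
2. an offset ``i < max_trim`` is *flagged* when any type exceeds
   ``m_t + max(k_mad * 1.4826 * s_t, abs_floor)``;
3. the trim length is ``1 + (largest flagged offset)``, or 0 when nothing is
   flagged.  Contiguity is not required: a damage curve may dip under the
   threshold and re-exceed it closer to the end.

The absolute floor guards against flagging statistically significant but
biologically negligible bumps; the MAD term guards against floors that are
small relative to counting noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
import pysam

from ._codec import BASES
from .io import ReferenceSet
from .sam import Columns, aligned_columns, mate_of, passes_filters

__all__ = [
    "MismatchProfile",
    "TrimSpec",
    "FlatnessParams",
    "InsufficientDataError",
    "detect_trim",
    "iterate_trim",
    "profiles_from_sam",
]

END5, END3 = 0, 1
_END_LABELS = ("5p", "3p")


class InsufficientDataError(ValueError):
    """Raised when an end has no baseline offsets with enough data."""


class TrimParameterError(ValueError):
    """Invalid flatness/trim parameter combination."""


@dataclass
class TrimSpec:
    """Bases to hard-trim from each end of each mate."""

    r1_5p: int = 0
    r1_3p: int = 0
    r2_5p: int = 0
    r2_3p: int = 0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def is_zero(self) -> bool:
        return not (self.r1_5p or self.r1_3p or self.r2_5p or self.r2_3p)

    def __add__(self, other: "TrimSpec") -> "TrimSpec":
        return TrimSpec(
            self.r1_5p + other.r1_5p,
            self.r1_3p + other.r1_3p,
            self.r2_5p + other.r2_5p,
            self.r2_3p + other.r2_3p,
        )

    def for_mate(self, mate: str) -> tuple[int, int]:
        return (self.r1_5p, self.r1_3p) if mate == "R1" else (self.r2_5p, self.r2_3p)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self)) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TrimSpec":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class FlatnessParams:
    """Parameters formalising "relatively constant and similar".

    ``baseline_window`` is an inclusive offset interval; ``None`` defaults to
    the outer half of the profile, ``[max_offset // 2, max_offset]``.
    ``abs_floor`` is an absolute per-type excess-frequency floor below which
    an elevation is never flagged.
    """

    baseline_window: tuple[int, int] | None = None
    k_mad: float = 3.0
    abs_floor: float = 0.002
    min_denom: int = 500
    max_trim: int = 40

    def __post_init__(self) -> None:
        if self.k_mad <= 0:
            raise TrimParameterError("k_mad must be positive")
        if self.max_trim < 0:
            raise TrimParameterError("max_trim must be non-negative")

    def window(self, max_offset: int) -> tuple[int, int]:
        lo, hi = self.baseline_window or (max_offset // 2, max_offset)
        if not (0 <= lo <= hi <= max_offset):
            raise TrimParameterError(
                f"baseline window {(lo, hi)} outside [0, {max_offset}]"
            )
        return lo, hi


class MismatchProfile:
    """12-type mismatch counts by distance from each read end, for one mate.

    ``counts`` has shape ``(2, 4, 4, max_offset + 1)`` indexed by
    (end, ref base, read base, offset); the diagonal (ref == read) is unused.
    ``denoms`` has shape ``(2, 4, max_offset + 1)``: comparable columns per
    reference base per offset.
    """

    def __init__(self, mate: str, max_offset: int = 50):
        if max_offset < 1:
            raise ValueError("max_offset must be >= 1")
        self.mate = mate
        self.max_offset = max_offset
        k = max_offset + 1
        self.counts = np.zeros((2, 4, 4, k), dtype=np.int64)
        self.denoms = np.zeros((2, 4, k), dtype=np.int64)

    # -- accumulation ------------------------------------------------------

    def add_arrays(
        self,
        offset5: np.ndarray,
        offset3: np.ndarray,
        ref_codes: np.ndarray,
        read_codes: np.ndarray,
    ) -> None:
        """Accumulate comparable columns given as parallel arrays."""
        k = self.max_offset + 1
        for end, off in ((END5, offset5), (END3, offset3)):
            sel = off <= self.max_offset
            if not sel.any():
                continue
            o = off[sel]
            rc = ref_codes[sel]
            qc = read_codes[sel]
            np.add.at(self.denoms[end], (rc, o), 1)
            mm = rc != qc
            if mm.any():
                np.add.at(self.counts[end], (rc[mm], qc[mm], o[mm]), 1)

    def add_columns(self, cols: Columns, trim: tuple[int, int] = (0, 0)) -> None:
        """Accumulate one alignment's columns, optionally behaving as if the
        read had already been trimmed by ``trim = (left, right)`` bases:
        trimmed offsets are masked out and the rest re-indexed."""
        left, right = trim
        o5, o3 = cols.offset5, cols.offset3
        rc, qc = cols.ref_codes, cols.read_codes
        if left or right:
            keep = (o5 >= left) & (o3 >= right)
            o5, o3 = o5[keep] - left, o3[keep] - right
            rc, qc = rc[keep], qc[keep]
        self.add_arrays(o5, o3, rc, qc)

    # -- derived quantities ------------------------------------------------

    def freq(self, end: int) -> np.ndarray:
        """Per-type frequencies, shape (4, 4, max_offset + 1); 0 where the
        denominator is 0."""
        denom = self.denoms[end][:, None, :].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.counts[end] / denom
        return np.nan_to_num(f, nan=0.0)

    def total_columns(self, end: int) -> np.ndarray:
        return self.denoms[end].sum(axis=0)

    # -- persistence -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for end in (END5, END3):
            freq = self.freq(end)
            for off in range(self.max_offset + 1):
                for r in range(4):
                    for a in range(4):
                        if r == a:
                            continue
                        rows.append(
                            (
                                _END_LABELS[end],
                                off,
                                BASES[r],
                                BASES[a],
                                int(self.counts[end, r, a, off]),
                                int(self.denoms[end, r, off]),
                                round(float(freq[r, a, off]), 6),
                            )
                        )
        return pd.DataFrame(
            rows, columns=["end", "offset", "ref", "alt", "count", "denom", "freq"]
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "w") as out:
            out.write(f"# mate={self.mate} max_offset={self.max_offset}\n")
            df.to_csv(out, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MismatchProfile":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
            df = pd.read_csv(fh, sep="\t")
        prof = cls(meta["mate"], int(meta["max_offset"]))
        base_idx = {b: i for i, b in enumerate(BASES)}
        end_idx = {lab: i for i, lab in enumerate(_END_LABELS)}
        for row in df.itertuples(index=False):
            e = end_idx[row.end]
            r = base_idx[row.ref]
            a = base_idx[row.alt]
            prof.counts[e, r, a, row.offset] = row.count
            prof.denoms[e, r, row.offset] = row.denom
        return prof


def profiles_from_sam(
    sam_path: str | Path,
    refset: ReferenceSet,
    max_offset: int = 50,
    mapq_min: int = 20,
    trim: TrimSpec | None = None,
) -> dict[str, MismatchProfile]:
    """Accumulate R1/R2 profiles over all eligible alignments in a SAM file."""
    profiles = {
        "R1": MismatchProfile("R1", max_offset),
        "R2": MismatchProfile("R2", max_offset),
    }
    trim = trim or TrimSpec()
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for aln in fh:
            if not passes_filters(aln, mapq_min):
                continue
            mate = mate_of(aln)
            prof = profiles.get(mate)
            if prof is None:
                continue
            prof.add_columns(aligned_columns(aln, refset), trim.for_mate(mate))
    return profiles


# ---------------------------------------------------------------------------
# trim detection


def _detect_end(
    profile: MismatchProfile, end: int, params: FlatnessParams
) -> tuple[int, dict]:
    k = profile.max_offset
    if params.max_trim > k:
        raise TrimParameterError(
            f"max_trim={params.max_trim} exceeds profile max_offset={k}"
        )
    lo, hi = params.window(k)
    freq = profile.freq(end)
    denoms = profile.denoms[end]
    window = np.arange(lo, hi + 1)

    baselines: dict[str, tuple[float, float, float]] = {}
    thresholds = np.full((4, 4), np.inf)
    any_baseline = False
    for r in range(4):
        ok = window[denoms[r, window] >= params.min_denom]
        if len(ok) == 0:
            continue
        any_baseline = True
        for a in range(4):
            if r == a:
                continue
            vals = freq[r, a, ok]
            m = float(np.median(vals))
            s = float(np.median(np.abs(vals - m)))
            thr = m + max(params.k_mad * 1.4826 * s, params.abs_floor)
            thresholds[r, a] = thr
            baselines[f"{BASES[r]}>{BASES[a]}"] = (m, s, thr)
    if not any_baseline:
        raise InsufficientDataError(
            f"{profile.mate} {_END_LABELS[end]}: no baseline offset in "
            f"[{lo}, {hi}] has denominator >= {params.min_denom}"
        )

    flagged: list[int] = []
    for i in range(min(params.max_trim, k + 1)):
        exceed = (freq[:, :, i] > thresholds) & (
            denoms[:, i][:, None] >= params.min_denom
        )
        if exceed.any():
            flagged.append(i)
    trim = (flagged[-1] + 1) if flagged else 0
    diag = {
        "flagged_offsets": flagged,
        "baselines": baselines,
        "window": (lo, hi),
        "trim": trim,
    }
    return trim, diag


def detect_trim(
    profile_r1: MismatchProfile,
    profile_r2: MismatchProfile,
    params: FlatnessParams | None = None,
) -> tuple[TrimSpec, dict]:
    """Detect hard-trim lengths for the four (mate, end) combinations.

    Returns the TrimSpec together with per-end diagnostics (flagged offsets
    and per-type baselines/thresholds).
    """
    params = params or FlatnessParams()
    if profile_r1.max_offset != profile_r2.max_offset:
        raise TrimParameterError("R1/R2 profiles have different max_offset")
    diagnostics: dict[str, dict] = {}
    trims = {}
    for prof, mate in ((profile_r1, "R1"), (profile_r2, "R2")):
        for end, lab in ((END5, "5p"), (END3, "3p")):
            t, diag = _detect_end(prof, end, params)
            trims[f"{mate.lower()}_{lab}"] = t
            diagnostics[f"{mate}_{lab}"] = diag
    return TrimSpec(**trims), diagnostics


@dataclass
class IterativeTrimResult:
    spec: TrimSpec
    converged: bool
    rounds: list[TrimSpec] = field(default_factory=list)
    profiles: dict[str, MismatchProfile] | None = None


def iterate_trim(
    sam_path: str | Path,
    refset: ReferenceSet,
    params: FlatnessParams | None = None,
    max_rounds: int = 5,
    max_offset: int = 50,
    mapq_min: int = 20,
) -> IterativeTrimResult:
    """Repeat profile -> detect -> virtual trim until the profile is flat.

    Trimmed offsets of the original alignments are masked (and the remainder
    re-indexed) rather than the reads being re-aligned; the cumulative
    TrimSpec is returned.  Convergence means a round detected nothing new.
    """
    params = params or FlatnessParams()
    cumulative = TrimSpec()
    rounds: list[TrimSpec] = []
    converged = False
    profiles: dict[str, MismatchProfile] | None = None
    for round_no in range(max_rounds):
        profiles = profiles_from_sam(
            sam_path, refset, max_offset=max_offset, mapq_min=mapq_min, trim=cumulative
        )
        try:
            spec, _diag = detect_trim(profiles["R1"], profiles["R2"], params)
        except InsufficientDataError:
            if round_no == 0:
                raise
            # earlier rounds trimmed so deep that no baseline remains;
            # stop with what has been accumulated
            break
        rounds.append(spec)
        if spec.is_zero():
            converged = True
            break
        cumulative = cumulative + spec
        # cap each end at max_trim; a capped end cannot converge further
        cumulative = TrimSpec(
            min(cumulative.r1_5p, params.max_trim),
            min(cumulative.r1_3p, params.max_trim),
            min(cumulative.r2_5p, params.max_trim),
            min(cumulative.r2_3p, params.max_trim),
        )
    return IterativeTrimResult(cumulative, converged, rounds, profiles)
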