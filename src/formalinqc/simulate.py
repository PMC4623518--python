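"""Synthetic formalin-damaged sequencing libraries with ground truth.

The generator emulates the phenomenology of short-fragment paired-end
libraries built from formalin-fixed, ethanol-stored museum specimens:

* short template fragments drawn from a two-component lognormal mixture
  (insert peaks near ~120 and ~240 bp, as seen on Bioanalyzer traces of such
  libraries);
* end-concentrated base misincorporation: every read base at distance ``i``
  from a read end is substituted with probability ``a * exp(-i / lam)``,
  independently for the 5' and 3' ends, with the substitute base drawn from
  a 12-type weight table conditioned on the true base (formalin mode:
  uniform over all types, so all 12 mismatch types rise at both ends;
  adna mode: C->T mass at 5' and G->T at 3');
* a constant per-base sequencing error rate ``e0`` (uniform random
  different base);
* PCR duplication: each emitted pair is, with probability ``dup_rate``, a
  copy of a previously emitted pair.  Damage lives on the template
  molecule, so copies share it; by default copies also share the baseline
  errors and are therefore exact sequence duplicates (see
  ``duplicate_errors``).

Because every read's true origin is known, the generator also emits a truth
SAM (all-M CIGARs, MAPQ 60) so the whole downstream pipeline can be
exercised and checked against brute-force oracles without an aligner.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
import pysam

from ._codec import BASES, COMPLEMENT, codes_to_seq, qual_to_string
from .damage import MismatchProfile, TrimSpec
from .io import ReadRecord, ReferenceSet, write_fastq

__all__ = [
    "DamageModel",
    "SimParams",
    "SimulatedLibrary",
    "SimulationParameterError",
    "make_reference",
    "simulate_library",
    "preset",
    "PRESETS",
]


class SimulationParameterError(ValueError):
    pass


def make_reference(
    length: int, gc: float, seed: int, name: str = "ref1"
) -> ReferenceSet:
    """Random reference with i.i.d. bases, P(G) = P(C) = gc / 2."""
    if length < 1000:
        raise SimulationParameterError("reference length must be >= 1000")
    if not (0.0 < gc < 1.0):
        raise SimulationParameterError("gc must be in the open interval (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2
    codes = rng.choice(4, size=length, p=[at, gc / 2, gc / 2, at]).astype(np.uint8)
    return ReferenceSet({name: codes_to_seq(codes)})


@dataclass
class DamageModel:
    """End-concentrated substitution model.

    ``a`` is the per-base extra substitution probability at offset 0 and
    ``lam`` the exponential length scale (bases).  ``weights5``/``weights3``
    are 4x4 ref-by-read weight tables over the 12 substitution types
    (diagonal ignored); the substitute base for a damage event at a base
    with true value X is drawn from the table row X renormalised — the
    "redraw until the type's ref base matches" scheme.  Rows with zero mass
    cannot be damaged (this is what restricts adna damage to C at 5' ends
    and G at 3' ends).
    """

    mode: str = "none"  # formalin | adna | none
    a: float = 0.0
    lam: float = 8.0
    weights5: Optional[np.ndarray] = None
    weights3: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 0.5):
            raise SimulationParameterError("damage amplitude a must be in [0, 0.5]")
        if self.lam <= 0:
            raise SimulationParameterError("decay length lam must be positive")
        if self.mode not in ("formalin", "adna", "none"):
            raise SimulationParameterError(f"unknown damage mode {self.mode!r}")
        uniform = np.ones((4, 4)) - np.eye(4)
        if self.mode == "formalin":
            default5 = default3 = uniform
        elif self.mode == "adna":
            ct = np.zeros((4, 4))
            ct[1, 3] = 1.0  # C -> T at 5'
            gt = np.zeros((4, 4))
            gt[2, 3] = 1.0  # G -> T at 3'
            default5, default3 = ct, gt
        else:
            default5 = default3 = uniform
        self.weights5 = np.asarray(
            self.weights5 if self.weights5 is not None else default5, dtype=float
        )
        self.weights3 = np.asarray(
            self.weights3 if self.weights3 is not None else default3, dtype=float
        )
        for w in (self.weights5, self.weights3):
            np.fill_diagonal(w, 0.0)
            total = w.sum()
            if total > 0:
                w /= total

    @classmethod
    def formalin(cls, a: float = 0.02, lam: float = 8.0) -> "DamageModel":
        return cls("formalin", a, lam)

    @classmethod
    def adna(cls, a: float = 0.02, lam: float = 8.0) -> "DamageModel":
        return cls("adna", a, lam)

    @classmethod
    def none(cls) -> "DamageModel":
        return cls("none", 0.0, 8.0)

    def expected_trim_point(self, abs_floor: float) -> int:
        """Offset at which the *total* excess substitution probability
        ``a * exp(-i / lam)`` decays to the detection floor:
        ``ceil(lam * ln(a / abs_floor))``.

        Each individual substitution type carries a third of the excess
        (uniform weights, three alternative bases), so its deterministic
        floor crossing is ``lam * ln 3`` (~9 bases for lam = 8) shallower;
        in practice flagging extinguishes near the *total* crossing, because
        between the two crossings the real residual damage still lifts
        enough per-type frequencies over the threshold at well-powered
        profile sizes.  See the methods notes for the derivation.
        """
        if self.a <= abs_floor:
            return 0
        return math.ceil(self.lam * math.log(self.a / abs_floor))


@dataclass
class SimParams:
    """Study conditions for one simulated library."""

    n_pairs: int
    reference: ReferenceSet | tuple[int, float] = (200_000, 0.40)
    read_len: int = 100
    frag_means: tuple[float, float] = (120.0, 240.0)
    frag_sigma_log: float = 0.25
    frag_weight: float = 0.5  # mixture weight of the first component
    min_frag: int = 35
    e0: float = 0.002
    dup_rate: float = 0.0
    damage: DamageModel = field(default_factory=DamageModel.none)
    qual: int = 35
    divergence: float = 0.0  # substitution rate of the sample vs the reference
    duplicate_errors: str = "shared"  # shared -> PCR copies are exact duplicates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise SimulationParameterError("n_pairs must be >= 1")
        if self.read_len < 30:
            raise SimulationParameterError("read_len must be >= 30")
        if not (0.0 <= self.dup_rate < 1.0):
            raise SimulationParameterError("dup_rate must be in [0, 1)")
        if self.duplicate_errors not in ("shared", "fresh"):
            raise SimulationParameterError("duplicate_errors must be shared|fresh")

    def to_json_dict(self) -> dict:
        d = {
            "n_pairs": self.n_pairs,
            "read_len": self.read_len,
            "frag_means": list(self.frag_means),
            "frag_sigma_log": self.frag_sigma_log,
            "frag_weight": self.frag_weight,
            "min_frag": self.min_frag,
            "e0": self.e0,
            "dup_rate": self.dup_rate,
            "qual": self.qual,
            "divergence": self.divergence,
            "duplicate_errors": self.duplicate_errors,
            "seed": self.seed,
            "damage": {
                "mode": self.damage.mode,
                "a": self.damage.a,
                "lam": self.damage.lam,
            },
        }
        if isinstance(self.reference, tuple):
            d["reference"] = {"length": self.reference[0], "gc": self.reference[1]}
        else:
            d["reference"] = {"names": self.reference.names}
        return d


PRESETS = {
    # a specimen that sequenced usably: heavy PCR duplication and clear
    # but trimmable end damage
    "good_specimen": dict(
        dup_rate=0.64, damage=("formalin", 0.02, 8.0), e0=0.002
    ),
    # a failed specimen: extreme duplication (97.5%), broad severe damage
    "failed_specimen": dict(
        dup_rate=0.975, damage=("formalin", 0.08, 15.0), e0=0.004
    ),
    "undamaged": dict(dup_rate=0.0, damage=("none", 0.0, 8.0), e0=0.002),
}


def preset(name: str, n_pairs: int = 50_000, seed: int = 1, **overrides) -> SimParams:
    """Named study conditions; extra keyword arguments override fields."""
    if name not in PRESETS:
        raise SimulationParameterError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        )
    cfg = PRESETS[name]
    mode, a, lam = cfg["damage"]
    params = SimParams(
        n_pairs=n_pairs,
        dup_rate=cfg["dup_rate"],
        e0=cfg["e0"],
        damage=DamageModel(mode, a, lam),
        seed=seed,
    )
    return replace(params, **overrides) if overrides else params


# ---------------------------------------------------------------------------


@dataclass
class _MateData:
    """Per-template read data for one mate, in sequenced-read orientation."""

    emit: np.ndarray  # (n_templates, read_len) uint8, 255 pad
    true: np.ndarray  # sample bases read-space, same shape
    ref: np.ndarray  # reference bases read-space, same shape
    rlen: np.ndarray  # (n_templates,)
    rstart: np.ndarray  # reference interval start per read
    rend: np.ndarray
    reverse: np.ndarray  # bool: maps to the minus strand


class SimulatedLibrary:
    """In-memory simulated library plus ground truth.

    Per-pair arrays index emitted pairs; per-template arrays index unique
    molecules (PCR copies point to their template via ``tid``).
    """

    def __init__(
        self,
        params: SimParams,
        refset: ReferenceSet,
        ref_name: str,
        mates: dict[str, _MateData],
        tid: np.ndarray,
        dup_of: np.ndarray,
        frag_start: np.ndarray,
        frag_end: np.ndarray,
        frag_strand: np.ndarray,
        template_events: pd.DataFrame,
        pair_events: pd.DataFrame,
        substitutions: pd.DataFrame,
        pair_error_layers: dict[str, np.ndarray] | None = None,
    ):
        self.params = params
        self.refset = refset
        self.ref_name = ref_name
        self._mates = mates
        self.tid = tid
        self.dup_of = dup_of
        self.frag_start = frag_start
        self.frag_end = frag_end
        self.frag_strand = frag_strand
        self.template_events = template_events
        self.pair_events = pair_events
        self.substitutions = substitutions
        self._pair_error_layers = pair_error_layers

    # -- basic accessors ---------------------------------------------------

    @property
    def n_pairs(self) -> int:
        return len(self.tid)

    @property
    def n_templates(self) -> int:
        return len(self._mates["R1"].rlen)

    def pair_matrix(self, mate: str) -> np.ndarray:
        """(n_pairs, read_len) emitted base codes for a mate (255 = pad)."""
        m = self._mates[mate]
        out = m.emit[self.tid]
        layers = self._pair_error_layers
        if layers is not None:
            out = out.copy()
            alt = layers[mate]
            mask = alt != 255
            out[mask] = alt[mask]
        return out

    def read_id(self, pair_idx: int) -> str:
        return f"sim{pair_idx:07d}"

    def read_records(self, mate: str) -> Iterator[ReadRecord]:
        mat = self.pair_matrix(mate)
        rlen = self._mates[mate].rlen[self.tid]
        q = self.params.qual
        for i in range(self.n_pairs):
            L = int(rlen[i])
            yield ReadRecord(
                self.read_id(i),
                codes_to_seq(mat[i, :L]),
                np.full(L, q, dtype=np.int16),
                mate,
            )

    def pairs(self) -> Iterator[tuple[ReadRecord, ReadRecord]]:
        yield from zip(self.read_records("R1"), self.read_records("R2"))

    # -- truth-side summaries ---------------------------------------------

    def read_intervals(self, mate: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-pair reference intervals [start, end) of the given mate."""
        m = self._mates[mate]
        return m.rstart[self.tid], m.rend[self.tid]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": np.arange(self.n_pairs),
                "template": self.tid,
                "ref": self.ref_name,
                "frag_start": self.frag_start[self.tid],
                "frag_end": self.frag_end[self.tid],
                "strand": np.where(self.frag_strand[self.tid], "-", "+"),
                "duplicate_of": self.dup_of,
            }
        )

    def events_per_pair(self) -> pd.DataFrame:
        """Expand template-level events through the duplication lineage and
        append any pair-level (fresh error) events."""
        frames = []
        te = self.template_events
        if len(te):
            mult = pd.DataFrame({"pair": np.arange(self.n_pairs), "template": self.tid})
            frames.append(mult.merge(te, on="template", how="inner"))
        pe = self.pair_events
        if len(pe):
            pe = pe.copy()
            pe["template"] = self.tid[pe["pair"].to_numpy()]
            frames.append(pe)
        if not frames:
            return pd.DataFrame(
                columns=["pair", "template", "mate", "offset", "true", "emitted", "cause"]
            )
        out = pd.concat(frames, ignore_index=True)
        return out[["pair", "template", "mate", "offset", "true", "emitted", "cause"]]

    # -- profiles (fast truth path) ----------------------------------------

    def mismatch_profile(
        self, mate: str, max_offset: int = 50, unique_templates: bool = False
    ) -> MismatchProfile:
        """Profile of emitted reads against the *reference*, accumulated
        directly from the truth matrices (identical to parsing the truth SAM,
        just without the file round-trip).

        With ``unique_templates=True`` each template molecule contributes
        once, which (in shared-error mode) equals profiling the library after
        exact-duplicate removal — PCR copies carry no independent evidence.
        """
        m = self._mates[mate]
        if unique_templates and self._pair_error_layers is None:
            sel = np.sort(np.unique(self.tid))
            emit = m.emit[sel]
            ref = m.ref[sel]
            rlen = m.rlen[sel]
        else:
            emit = self.pair_matrix(mate)
            ref = m.ref[self.tid]
            rlen = m.rlen[self.tid]
        prof = MismatchProfile(mate, max_offset)
        k = max_offset + 1
        L = emit.shape[1]
        valid = np.arange(L)[None, :] < rlen[:, None]

        def _accumulate(end: int, emit_m: np.ndarray, ref_m: np.ndarray, val: np.ndarray):
            cols = min(L, k)
            e = emit_m[:, :cols]
            r = ref_m[:, :cols]
            v = val[:, :cols] & (e < 4) & (r < 4)
            for rb in range(4):
                sel = v & (r == rb)
                prof.denoms[end, rb, :cols] += sel.sum(axis=0)
                mm = sel & (e != rb)
                if mm.any():
                    for ab in range(4):
                        if ab == rb:
                            continue
                        prof.counts[end, rb, ab, :cols] += (mm & (e == ab)).sum(axis=0)

        _accumulate(0, emit, ref, valid)
        # right-align rows for the 3' table
        idx = rlen[:, None] - 1 - np.arange(L)[None, :]
        ok = idx >= 0
        idx_c = np.clip(idx, 0, L - 1)
        rows = np.arange(len(emit))[:, None]
        emit_r = np.where(ok, emit[rows, idx_c], 255).astype(np.uint8)
        ref_r = np.where(ok, ref[rows, idx_c], 255).astype(np.uint8)
        _accumulate(1, emit_r, ref_r, ok)
        return prof

    # -- trimming ----------------------------------------------------------

    def trimmed(self, spec: TrimSpec, min_len: int = 30) -> "SimulatedLibrary":
        """New library whose reads (and truth coordinates) are hard-trimmed;
        pairs with a mate shorter than ``min_len`` are dropped."""
        new_mates: dict[str, _MateData] = {}
        keep_t = np.ones(self.n_templates, dtype=bool)
        for mate in ("R1", "R2"):
            left, right = spec.for_mate(mate)
            m = self._mates[mate]
            keep_t &= (m.rlen - left - right) >= min_len
        for mate in ("R1", "R2"):
            left, right = spec.for_mate(mate)
            m = self._mates[mate]
            L = m.emit.shape[1]
            new_len = np.maximum(m.rlen - left - right, 0)
            sl = slice(left, L - right if right else L)
            rstart = np.where(m.reverse, m.rstart + right, m.rstart + left)
            rend = np.where(m.reverse, m.rend - left, m.rend - right)
            new_mates[mate] = _MateData(
                emit=np.ascontiguousarray(m.emit[:, sl]),
                true=np.ascontiguousarray(m.true[:, sl]),
                ref=np.ascontiguousarray(m.ref[:, sl]),
                rlen=new_len,
                rstart=rstart,
                rend=rend,
                reverse=m.reverse,
            )
        keep_p = keep_t[self.tid]
        layers = None
        if self._pair_error_layers is not None:
            layers = {}
            for mate in ("R1", "R2"):
                left, right = spec.for_mate(mate)
                arr = self._pair_error_layers[mate]
                L = arr.shape[1]
                layers[mate] = np.ascontiguousarray(
                    arr[keep_p, left : L - right if right else L]
                )
        # re-number pairs; template-level arrays stay (unused rows harmless)
        return SimulatedLibrary(
            self.params,
            self.refset,
            self.ref_name,
            new_mates,
            self.tid[keep_p],
            self.dup_of[keep_p],
            self.frag_start,
            self.frag_end,
            self.frag_strand,
            pd.DataFrame(columns=self.template_events.columns),
            pd.DataFrame(columns=self.pair_events.columns),
            self.substitutions,
            layers,
        )

    # -- writers -----------------------------------------------------------

    def write_fastq(self, prefix: str | Path, gzip_out: bool = True) -> tuple[Path, Path]:
        suffix = ".fastq.gz" if gzip_out else ".fastq"
        p1 = Path(f"{prefix}_R1{suffix}")
        p2 = Path(f"{prefix}_R2{suffix}")
        write_fastq(self.read_records("R1"), p1)
        write_fastq(self.read_records("R2"), p2)
        return p1, p2

    def write_truth_sam(self, path: str | Path) -> Path:
        """Error-free-coordinate alignments of every emitted read."""
        path = Path(path)
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": len(seq)} for name, seq in self.refset.items()
            ],
        }
        qual = self.params.qual
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            mats = {m: self.pair_matrix(m) for m in ("R1", "R2")}
            for i in range(self.n_pairs):
                t = self.tid[i]
                segs = []
                for mate in ("R1", "R2"):
                    m = self._mates[mate]
                    L = int(m.rlen[t])
                    codes = mats[mate][i, :L]
                    rev = bool(m.reverse[t])
                    if rev:
                        codes = COMPLEMENT[codes[::-1]]
                    seg = pysam.AlignedSegment(out.header)
                    seg.query_name = self.read_id(i)
                    seg.query_sequence = codes_to_seq(codes)
                    seg.query_qualities = pysam.qualitystring_to_array(
                        qual_to_string(np.full(L, qual))
                    )
                    seg.reference_name = self.ref_name
                    seg.reference_start = int(m.rstart[t])
                    seg.cigartuples = [(0, L)]
                    seg.mapping_quality = 60
                    flag = 0x1 | 0x2 | (0x40 if mate == "R1" else 0x80)
                    if rev:
                        flag |= 0x10
                    other = "R2" if mate == "R1" else "R1"
                    if self._mates[other].reverse[t]:
                        flag |= 0x20
                    seg.flag = flag
                    segs.append(seg)
                segs[0].next_reference_name = self.ref_name
                segs[0].next_reference_start = segs[1].reference_start
                segs[1].next_reference_name = self.ref_name
                segs[1].next_reference_start = segs[0].reference_start
                out.write(segs[0])
                out.write(segs[1])
        return path

    def write_truth_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.truth_frame().to_csv(path, sep="\t", index=False)
        return path

    def write_params_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.params.to_json_dict(), indent=2) + "\n")
        return path

    # -- oracles over truth intervals (used by coverage/error checks) ------

    def oracle_depth(self) -> np.ndarray:
        """Per-position depth implied by the truth read intervals."""
        L = self.refset.length(self.ref_name)
        diff = np.zeros(L + 1, dtype=np.int64)
        for mate in ("R1", "R2"):
            s, e = self.read_intervals(mate)
            np.add.at(diff, s, 1)
            np.add.at(diff, e, -1)
        return np.cumsum(diff[:-1])


# ---------------------------------------------------------------------------


def _sample_fragments(params: SimParams, rng: np.random.Generator, n: int, ref_len: int):
    comp = rng.random(n) >= params.frag_weight
    mu = np.where(comp, math.log(params.frag_means[1]), math.log(params.frag_means[0]))
    lengths = np.rint(np.exp(rng.normal(mu, params.frag_sigma_log))).astype(np.int64)
    lengths = np.maximum(lengths, params.min_frag)
    if (lengths > ref_len).any():
        raise SimulationParameterError(
            f"reference (length {ref_len}) is shorter than the longest sampled "
            f"fragment ({int(lengths.max())})"
        )
    starts = (rng.random(n) * (ref_len - lengths + 1)).astype(np.int64)
    strands = rng.random(n) < 0.5  # True -> minus strand
    return starts, starts + lengths, strands


def _conditional_alt(
    weights: np.ndarray, true_codes: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Draw substitute bases from a 12-type weight table conditioned on the
    true base (rows renormalised; caller guarantees positive row mass)."""
    rows = weights[true_codes]  # (n, 4)
    cdf = np.cumsum(rows, axis=1)
    cdf /= cdf[:, -1:]
    u = np.clip(u, 1e-12, None)  # u == 0 exactly must not select the true base
    return (cdf < u[:, None]).sum(axis=1).astype(np.uint8)


def _apply_damage_and_errors(
    mate: _MateData,
    params: SimParams,
    rng: np.random.Generator,
    events: list,
    mate_label: str,
) -> None:
    """Mutate ``mate.emit`` in place with end damage and (shared-mode)
    baseline errors; append truth events."""
    dm = params.damage
    n, L = mate.true.shape
    j = np.arange(L)[None, :]
    valid = j < mate.rlen[:, None]
    emit = mate.true.copy()

    damage_mask = np.zeros((n, L), dtype=bool)
    if dm.a > 0:
        # uniforms are drawn as full matrices *before* masking so that, for a
        # fixed seed, raising the amplitude only ever adds damage events
        # (monotone coupling) without re-randomising the existing ones
        u5, u3 = rng.random((n, L)), rng.random((n, L))
        ualt5, ualt3 = rng.random((n, L)), rng.random((n, L))
        p5 = dm.a * np.exp(-j / dm.lam)
        off3 = mate.rlen[:, None] - 1 - j
        p3 = dm.a * np.exp(-np.maximum(off3, 0) / dm.lam)
        mass5 = dm.weights5.sum(axis=1)
        mass3 = dm.weights3.sum(axis=1)
        d5 = (u5 < p5) & valid & (mass5[mate.true.clip(max=3)] > 0) & (mate.true < 4)
        d3 = (u3 < p3) & valid & (mass3[mate.true.clip(max=3)] > 0) & (mate.true < 4) & ~d5
        for mask, weights, ualt in ((d5, dm.weights5, ualt5), (d3, dm.weights3, ualt3)):
            if not mask.any():
                continue
            rows, cols = np.nonzero(mask)
            true_codes = mate.true[rows, cols]
            alts = _conditional_alt(weights, true_codes, ualt[rows, cols])
            emit[rows, cols] = alts
            for r, c, t, a in zip(rows, cols, true_codes, alts):
                events.append((int(r), mate_label, int(c), BASES[t], BASES[a], "damage"))
        damage_mask = d5 | d3

    if params.e0 > 0 and params.duplicate_errors == "shared":
        _apply_error_layer(emit, mate.true, valid & ~damage_mask, params, rng, events, mate_label)
    mate.emit = emit


def _apply_error_layer(
    emit: np.ndarray,
    true: np.ndarray,
    allowed: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
    events: list,
    mate_label: str,
) -> None:
    u_err = rng.random(emit.shape)
    u_alt = rng.random(emit.shape)
    err = (u_err < params.e0) & allowed & (true < 4)
    if not err.any():
        return
    rows, cols = np.nonzero(err)
    true_codes = true[rows, cols]
    alts = ((true_codes + 1 + (u_alt[rows, cols] * 3).astype(np.uint8)) % 4).astype(
        np.uint8
    )
    emit[rows, cols] = alts
    for r, c, t, a in zip(rows, cols, true_codes, alts):
        events.append((int(r), mate_label, int(c), BASES[t], BASES[a], "error"))


def simulate_library(params: SimParams) -> SimulatedLibrary:
    """Generate a library under the given study conditions (deterministic
    for a given seed)."""
    rng = np.random.default_rng(params.seed)

    if isinstance(params.reference, ReferenceSet):
        refset = params.reference
    else:
        length, gc = params.reference
        refset = make_reference(length, gc, int(rng.integers(2**31)))
    ref_name = refset.names[0]
    ref_codes = refset.codes(ref_name)
    ref_len = len(ref_codes)

    # sample genome: reference plus optional true substitutions
    if params.divergence > 0:
        pos = np.nonzero(rng.random(ref_len) < params.divergence)[0]
        orig = ref_codes[pos]
        new = ((orig + 1 + (rng.random(len(pos)) * 3).astype(np.uint8)) % 4).astype(
            np.uint8
        )
        sample_codes = ref_codes.copy()
        sample_codes[pos] = new
        substitutions = pd.DataFrame(
            {
                "pos": pos,
                "ref": [BASES[c] for c in orig],
                "alt": [BASES[c] for c in new],
            }
        )
    else:
        sample_codes = ref_codes
        substitutions = pd.DataFrame(columns=["pos", "ref", "alt"])

    # duplication lineage: of the n emitted pairs, Binomial(n, dup_rate) are
    # PCR copies; copy slots are spread uniformly over the templates, so
    # per-template copy numbers are 1 + ~Poisson(d/(1-d)) and the measured
    # exact-duplicate fraction is Binomial(n, dup_rate)/n.  The first
    # in-stream occurrence of a template is the original.
    n = params.n_pairs
    k = int(np.count_nonzero(rng.random(n) < params.dup_rate))
    k = min(k, n - 1)
    n_templates = n - k
    tid_all = np.concatenate(
        [np.arange(n_templates), rng.integers(0, n_templates, size=k)]
    )
    tid = tid_all[rng.permutation(n)]
    dup_of = np.full(n, -1, dtype=np.int64)
    first_idx = np.full(n_templates, -1, dtype=np.int64)
    for i in range(n):
        t = tid[i]
        if first_idx[t] < 0:
            first_idx[t] = i
        else:
            dup_of[i] = first_idx[t]

    f_start, f_end, f_strand = _sample_fragments(params, rng, n_templates, ref_len)
    flen = f_end - f_start
    rlen = np.minimum(flen, params.read_len).astype(np.int64)
    L = params.read_len
    cols = np.arange(L)[None, :]

    mates: dict[str, _MateData] = {}
    for mate in ("R1", "R2"):
        # R1 reads the fragment's sequenced strand from its 5' end; R2 reads
        # the reverse complement.  On the reference this means:
        if mate == "R1":
            forward = ~f_strand  # plus-strand fragments give forward R1
        else:
            forward = f_strand
        rstart = np.where(forward, f_start, f_end - rlen)
        rend = np.where(forward, f_start + rlen, f_end)
        pos_f = rstart[:, None] + cols
        pos_r = (rend - 1)[:, None] - cols
        pos = np.where(forward[:, None], pos_f, pos_r)
        in_read = cols < rlen[:, None]
        pos_c = np.clip(pos, 0, ref_len - 1)
        true = sample_codes[pos_c]
        refm = ref_codes[pos_c]
        rev_rows = ~forward
        true[rev_rows] = COMPLEMENT[true[rev_rows]]
        refm[rev_rows] = COMPLEMENT[refm[rev_rows]]
        true = np.where(in_read, true, 255).astype(np.uint8)
        refm = np.where(in_read, refm, 255).astype(np.uint8)
        mates[mate] = _MateData(
            emit=true.copy(),
            true=true,
            ref=refm,
            rlen=rlen,
            rstart=rstart,
            rend=rend,
            reverse=~forward,
        )

    template_events: list = []
    for mate_label in ("R1", "R2"):
        _apply_damage_and_errors(mates[mate_label], params, rng, template_events, mate_label)

    pair_events: list = []
    pair_layers: dict[str, np.ndarray] | None = None
    if params.e0 > 0 and params.duplicate_errors == "fresh":
        pair_layers = {}
        for mate_label in ("R1", "R2"):
            m = mates[mate_label]
            layer = np.full((n, L), 255, dtype=np.uint8)
            base = m.emit[tid]
            valid = cols < m.rlen[tid][:, None]
            damaged = m.emit != m.true
            allowed = valid & ~damaged[tid]
            ev: list = []
            tmp = base.copy()
            _apply_error_layer(tmp, m.true[tid], allowed, params, rng, ev, mate_label)
            changed = tmp != base
            layer[changed] = tmp[changed]
            pair_layers[mate_label] = layer
            pair_events.extend((int(p), ml, off, t, a, c) for p, ml, off, t, a, c in ev)

    te = pd.DataFrame(
        template_events,
        columns=["template", "mate", "offset", "true", "emitted", "cause"],
    )
    pe = pd.DataFrame(
        pair_events, columns=["pair", "mate", "offset", "true", "emitted", "cause"]
    )

    return SimulatedLibrary(
        params,
        refset,
        ref_name,
        mates,
        tid,
        dup_of,
        f_start,
        f_end,
        f_strand,
        te,
        pe,
        substitutions,
        pair_layers,
    )
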