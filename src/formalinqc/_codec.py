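"""Base encoding shared across the package.

Bases are coded A=0, C=1, G=2, T=3, N=4.  With this layout the Watson-Crick
complement of a non-N code is simply ``3 - code``, which the vectorised
read-space conversions rely on.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

#: char byte -> code, 255 for anything that is not ACGTN (case-insensitive)
_CHAR_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CHAR_TO_CODE[ord(_b)] = _i
    _CHAR_TO_CODE[ord(_b.lower())] = _i

_CODE_TO_CHAR = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)

#: code -> complement code (N stays N)
COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def seq_to_codes(seq: str, *, strict: bool = True) -> np.ndarray:
    """Encode a sequence string as a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CHAR_TO_CODE[raw]
    if strict and (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGTN symbol {bad!r} in sequence")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return _CODE_TO_CHAR[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return codes_to_seq(revcomp_codes(seq_to_codes(seq, strict=False)))


def qual_to_string(qual: np.ndarray) -> str:
    return (np.asarray(qual, dtype=np.uint8) + 33).tobytes().decode("ascii")


def string_to_qual(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
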