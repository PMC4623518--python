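import textwrap
from pathlib import Path

import numpy as np
import pytest

from formalinqc.io import ReferenceSet


@pytest.fixture
def tiny_ref() -> ReferenceSet:
    return ReferenceSet({"chr1": "ACGTACGTACGTACGTACGT"})


def write_sam(path: Path, refs: dict[str, int], records: list[str]) -> Path:
    """Write a minimal SAM file from header lengths and record lines."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in refs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.extend(records)
    path.write_text("\n".join(lines) + "\n")
    return path


def sam_record(
    qname: str,
    flag: int,
    ref: str,
    pos1: int,
    cigar: str,
    seq: str,
    mapq: int = 60,
    qual: str | None = None,
    tags: str = "",
) -> str:
    qual = qual or "I" * len(seq)
    rec = f"{qname}\t{flag}\t{ref}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}"
    if tags:
        rec += "\t" + tags
    return rec


@pytest.fixture
def sam_factory(tmp_path):
    def _make(refs: dict[str, int], records: list[str], name: str = "test.sam") -> Path:
        return write_sam(tmp_path / name, refs, records)

    return _make
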