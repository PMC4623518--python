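"""Naive brute-force oracles, kept deliberately independent of the package's
vectorised implementations: plain Python string walks over the simulator's
ground truth."""

from collections import Counter

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_read_layout(lib):
    """Per (pair, mate): (read sequence in read-space, reference interval,
    maps_reverse) recomputed from truth coordinates and the raw reference
    string only."""
    ref = lib.refset[lib.ref_name]
    truth = lib.truth_frame()
    reads = {"R1": list(lib.read_records("R1")), "R2": list(lib.read_records("R2"))}
    layout = {}
    for row in truth.itertuples(index=False):
        i = row.pair
        for mate in ("R1", "R2"):
            rec = reads[mate][i]
            rlen = len(rec.seq)
            forward = (row.strand == "+") == (mate == "R1")
            if forward:
                start, end = row.frag_start, row.frag_start + rlen
            else:
                start, end = row.frag_end - rlen, row.frag_end
            layout[(i, mate)] = (rec.seq, start, end, not forward)
    return layout


def oracle_mismatches(lib):
    """Multiset of read-space mismatch observations vs the reference, plus
    total aligned-base count, per mate."""
    ref = lib.refset[lib.ref_name]
    obs = {"R1": Counter(), "R2": Counter()}
    aligned = {"R1": 0, "R2": 0}
    for (i, mate), (seq, start, end, reverse) in oracle_read_layout(lib).items():
        ref_slice = ref[start:end]
        if reverse:
            ref_slice = revcomp(ref_slice)
        for off5, (rb, qb) in enumerate(zip(ref_slice, seq)):
            if rb == "N" or qb == "N":
                continue
            aligned[mate] += 1
            if rb != qb:
                obs[mate][(rb, qb, off5, len(seq) - 1 - off5)] += 1
    return obs, aligned


def oracle_profile_counts(lib, max_offset=50):
    """(end, ref, alt, offset) mismatch counts and (end, ref, offset)
    denominators per mate, brute force."""
    ref = lib.refset[lib.ref_name]
    counts = {"R1": Counter(), "R2": Counter()}
    denoms = {"R1": Counter(), "R2": Counter()}
    for (i, mate), (seq, start, end, reverse) in oracle_read_layout(lib).items():
        ref_slice = ref[start:end]
        if reverse:
            ref_slice = revcomp(ref_slice)
        L = len(seq)
        for off5, (rb, qb) in enumerate(zip(ref_slice, seq)):
            if rb == "N" or qb == "N":
                continue
            off3 = L - 1 - off5
            for endi, off in ((0, off5), (1, off3)):
                if off <= max_offset:
                    denoms[mate][(endi, rb, off)] += 1
                    if rb != qb:
                        counts[mate][(endi, rb, qb, off)] += 1
    return counts, denoms


def oracle_depth(lib):
    """Per-position depth from truth read intervals (interval stabbing)."""
    depth = [0] * len(lib.refset[lib.ref_name])
    for (_, _), (_, start, end, _) in oracle_read_layout(lib).items():
        for p in range(start, end):
            depth[p] += 1
    return depth


def oracle_error_counts(lib, start, end):
    """(mismatched, aligned) base counts within a reference window."""
    ref = lib.refset[lib.ref_name]
    mism = 0
    aligned = 0
    for (_, _), (seq, s, e, reverse) in oracle_read_layout(lib).items():
        ref_slice = ref[s:e]
        read = revcomp(seq) if reverse else seq  # reference orientation
        for k, (rb, qb) in enumerate(zip(ref_slice, read)):
            pos = s + k
            if not (start <= pos < end):
                continue
            if rb == "N" or qb == "N":
                continue
            aligned += 1
            if rb != qb:
                mism += 1
    return mism, aligned
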