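"""Mismatch-profile accumulation and data-driven trim detection."""

import numpy as np
import pytest

from formalinqc import simulate as sim
from formalinqc._codec import BASES
from formalinqc.damage import (
    END3,
    END5,
    FlatnessParams,
    InsufficientDataError,
    MismatchProfile,
    TrimSpec,
    detect_trim,
    iterate_trim,
)

B = {b: i for i, b in enumerate(BASES)}


def flat_profile(mate="R1", max_offset=50, denom=10_000, baseline=0.0):
    """Profile with uniform denominators and a constant per-type frequency."""
    p = MismatchProfile(mate, max_offset)
    p.denoms[:, :, :] = denom
    if baseline:
        p.counts[:, :, :, :] = int(round(baseline * denom))
        for b in range(4):
            p.counts[:, b, b, :] = 0
    return p


# ---------------------------------------------------------------------------
# accumulation and export


def test_zero_profile_denominators():
    """1000 full-length error-free reads: freq == 0 everywhere and every
    offset sees all 1000 reads in the denominator."""
    p = MismatchProfile("R1", 50)
    rng = np.random.default_rng(0)
    for _ in range(1000):
        codes = rng.integers(0, 4, size=100).astype(np.uint8)
        off5 = np.arange(100)
        p.add_arrays(off5, 99 - off5, codes, codes)
    assert p.counts.sum() == 0
    for end in (END5, END3):
        assert np.all(p.total_columns(end) == 1000)
        assert np.all(p.freq(end) == 0.0)


def test_single_observation_lands_in_5p_table_only():
    p = MismatchProfile("R1", 50)
    p.add_arrays(
        np.array([0]), np.array([99]), np.array([B["C"]]), np.array([B["T"]])
    )
    assert p.counts[END5, B["C"], B["T"], 0] == 1
    assert p.counts[END3].sum() == 0  # offset3=99 beyond max_offset
    assert p.denoms[END5, B["C"], 0] == 1


def test_export_row_count_and_round_trip(tmp_path):
    p = flat_profile(max_offset=2, denom=100, baseline=0.01)
    df = p.to_frame()
    assert len(df) == 2 * 3 * 12  # ends x offsets x types
    path = tmp_path / "prof.tsv"
    p.to_tsv(path)
    q = MismatchProfile.from_tsv(path)
    assert q.mate == p.mate and q.max_offset == p.max_offset
    assert np.array_equal(q.counts, p.counts)
    assert np.array_equal(q.denoms, p.denoms)


def test_export_freq_column_matches_counts(tmp_path):
    rng = np.random.default_rng(5)
    p = MismatchProfile("R2", 5)
    p.denoms[:, :, :] = rng.integers(500, 2000, size=p.denoms.shape)
    p.counts[:, :, :, :] = rng.integers(0, 5, size=p.counts.shape)
    for b in range(4):
        p.counts[:, b, b, :] = 0
    df = p.to_frame()
    for row in df.itertuples(index=False):
        assert row.freq == pytest.approx(row.count / row.denom, abs=1e-6)


# ---------------------------------------------------------------------------
# trim detection


def test_flat_profiles_detect_nothing():
    spec, diag = detect_trim(flat_profile("R1"), flat_profile("R2", baseline=0.001))
    assert spec == TrimSpec(0, 0, 0, 0)
    assert all(d["flagged_offsets"] == [] for d in diag.values())


def test_hand_constructed_elevation_trimmed_exactly():
    """C->T at 5% over offsets 0-4 of the R1 5' end, 0.2% baseline
    everywhere else: the rule trims exactly 5 bases there and nothing
    elsewhere."""
    p1 = flat_profile("R1", baseline=0.002)
    p2 = flat_profile("R2", baseline=0.002)
    p1.counts[END5, B["C"], B["T"], 0:5] = int(0.05 * 10_000)
    spec, diag = detect_trim(p1, p2)
    assert spec == TrimSpec(r1_5p=5, r1_3p=0, r2_5p=0, r2_3p=0)
    assert diag["R1_5p"]["flagged_offsets"] == [0, 1, 2, 3, 4]


def test_noncontiguous_flags_use_largest_offset():
    p1 = flat_profile("R1", baseline=0.002)
    p2 = flat_profile("R2", baseline=0.002)
    p1.counts[END3, B["G"], B["T"], [0, 7]] = 500  # dip between two peaks
    spec, _ = detect_trim(p1, p2)
    assert spec.r1_3p == 8


def test_insufficient_baseline_data_raises():
    p1 = flat_profile("R1", denom=100)  # below min_denom=500
    p2 = flat_profile("R2")
    with pytest.raises(InsufficientDataError, match="R1"):
        detect_trim(p1, p2)


def test_max_trim_beyond_profile_rejected():
    with pytest.raises(ValueError, match="max_trim"):
        detect_trim(
            flat_profile("R1"), flat_profile("R2"), FlatnessParams(max_trim=60)
        )


def test_detected_trim_tracks_injected_decay():
    """Formalin-type damage with amplitude a and decay lam is trimmed close
    to the offset where the injected excess decays to the floor."""
    params = sim.SimParams(
        n_pairs=30_000,
        e0=0.002,
        damage=sim.DamageModel.formalin(0.02, 8.0),
        seed=2,
    )
    lib = sim.simulate_library(params)
    spec, _ = detect_trim(
        lib.mismatch_profile("R1"), lib.mismatch_profile("R2")
    )
    expected = params.damage.expected_trim_point(0.002)
    for t in (spec.r1_5p, spec.r1_3p, spec.r2_5p, spec.r2_3p):
        assert abs(t - expected) <= 5


def test_trim_monotone_in_damage_amplitude():
    """More injected damage never shortens any detected trim (coupled
    seeds)."""
    prev = None
    for a in (0.005, 0.02, 0.08):
        p = sim.SimParams(
            n_pairs=15_000,
            e0=0.0,
            damage=sim.DamageModel.formalin(a, 8.0),
            seed=42,
        )
        lib = sim.simulate_library(p)
        s, _ = detect_trim(lib.mismatch_profile("R1"), lib.mismatch_profile("R2"))
        t = (s.r1_5p, s.r1_3p, s.r2_5p, s.r2_3p)
        if prev is not None:
            assert all(x >= y for x, y in zip(t, prev))
        prev = t


def test_profile_counts_match_oracle_mismatch_columns():
    """Sum of per-type counts at each offset equals the brute-force
    mismatch-column count."""
    from oracles import oracle_profile_counts

    lib = sim.simulate_library(
        sim.SimParams(n_pairs=400, e0=0.01, damage=sim.DamageModel.formalin(0.05), seed=9)
    )
    counts, denoms = oracle_profile_counts(lib)
    for mate in ("R1", "R2"):
        prof = lib.mismatch_profile(mate)
        for (endi, rb, qb, off), c in counts[mate].items():
            assert prof.counts[endi, B[rb], B[qb], off] == c
        assert prof.counts.sum() == sum(counts[mate].values())
        for (endi, rb, off), d in denoms[mate].items():
            assert prof.denoms[endi, B[rb], off] == d


# ---------------------------------------------------------------------------
# iterative trimming


def test_iterate_trim_zero_damage_converges_immediately(tmp_path):
    lib = sim.simulate_library(sim.preset("undamaged", n_pairs=20_000, seed=4))
    sam = lib.write_truth_sam(tmp_path / "u.sam")
    res = iterate_trim(sam, lib.refset)
    assert res.converged
    assert len(res.rounds) == 1
    assert res.spec == TrimSpec(0, 0, 0, 0)


def test_iterate_trim_single_exponential_converges(tmp_path):
    lib = sim.simulate_library(
        sim.SimParams(
            n_pairs=15_000, e0=0.002, damage=sim.DamageModel.formalin(0.02, 8.0), seed=6
        )
    )
    sam = lib.write_truth_sam(tmp_path / "d.sam")
    single, _ = detect_trim(lib.mismatch_profile("R1"), lib.mismatch_profile("R2"))
    res = iterate_trim(sam, lib.refset)
    assert res.converged and len(res.rounds) <= 3
    for got, one in zip(
        (res.spec.r1_5p, res.spec.r1_3p, res.spec.r2_5p, res.spec.r2_3p),
        (single.r1_5p, single.r1_3p, single.r2_5p, single.r2_3p),
    ):
        assert abs(got - one) <= 3


def test_trimspec_json_round_trip(tmp_path):
    spec = TrimSpec(6, 30, 17, 30)
    p = tmp_path / "spec.json"
    spec.to_json(p)
    assert TrimSpec.from_json(p) == spec
    assert p.read_text().strip() == '{"r1_5p": 6, "r1_3p": 30, "r2_5p": 17, "r2_3p": 30}'
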