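"""The synthetic formalin-damage library generator and its ground truth."""

from collections import Counter

import numpy as np
import pytest

from formalinqc import simulate as sim
from formalinqc.damage import detect_trim
from formalinqc.readproc import remove_duplicates
from formalinqc.sam import extract_mismatches, read_alignments


# ---------------------------------------------------------------------------
# make_reference


def test_reference_gc_and_determinism():
    a = sim.make_reference(100_000, 0.40, seed=1)
    b = sim.make_reference(100_000, 0.40, seed=1)
    assert a["ref1"] == b["ref1"]
    gc = (a["ref1"].count("G") + a["ref1"].count("C")) / 100_000
    assert gc == pytest.approx(0.40, abs=0.006)


def test_reference_parameter_validation():
    with pytest.raises(sim.SimulationParameterError):
        sim.make_reference(100_000, 1.0, seed=1)  # open interval
    with pytest.raises(sim.SimulationParameterError):
        sim.make_reference(500, 0.4, seed=1)


def test_reference_shorter_than_fragments_rejected():
    ref = sim.make_reference(1000, 0.4, seed=1)
    with pytest.raises(sim.SimulationParameterError, match="shorter"):
        sim.simulate_library(
            sim.SimParams(n_pairs=100, reference=ref, frag_means=(1500.0, 1500.0), seed=1)
        )


# ---------------------------------------------------------------------------
# presets


def test_preset_parameters():
    assert sim.preset("undamaged").damage.mode == "none"
    assert sim.preset("good_specimen").dup_rate == 0.64
    assert sim.preset("failed_specimen").dup_rate == 0.975
    with pytest.raises(sim.SimulationParameterError):
        sim.preset("no_such_thing")


# ---------------------------------------------------------------------------
# simulate_library


def test_determinism_byte_identical(tmp_path):
    params = sim.preset("good_specimen", n_pairs=500, seed=9)
    for d in ("a", "b"):
        (tmp_path / d).mkdir()
        lib = sim.simulate_library(params)
        lib.write_fastq(tmp_path / d / "sim")
        lib.write_truth_sam(tmp_path / d / "sim.sam")
    for name in ("sim_R1.fastq.gz", "sim_R2.fastq.gz", "sim.sam"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_no_damage_no_error_means_no_mismatches(tmp_path):
    lib = sim.simulate_library(sim.SimParams(n_pairs=100, e0=0.0, seed=2))
    sam = lib.write_truth_sam(tmp_path / "c.sam")
    total = 0
    for aln in read_alignments(sam, lib.refset):
        obs, _ = extract_mismatches(aln, lib.refset)
        total += len(obs)
    assert total == 0


def test_truth_events_biject_with_observed_mismatches(tmp_path):
    """Every mismatch seen in the truth SAM corresponds to exactly one
    injected event and vice versa."""
    lib = sim.simulate_library(
        sim.SimParams(
            n_pairs=600,
            dup_rate=0.5,
            e0=0.004,
            damage=sim.DamageModel.formalin(0.03, 8.0),
            seed=5,
        )
    )
    sam = lib.write_truth_sam(tmp_path / "b.sam")
    observed: Counter = Counter()
    reads = {}
    for aln in read_alignments(sam, lib.refset):
        mate = "R2" if aln.is_read2 else "R1"
        idx = int(aln.query_name[3:])
        obs, _ = extract_mismatches(aln, lib.refset)
        for o in obs:
            observed[(idx, mate, o.offset5, o.ref_base, o.read_base)] += 1
    expected: Counter = Counter()
    for row in lib.events_per_pair().itertuples(index=False):
        expected[(row.pair, row.mate, row.offset, row.true, row.emitted)] += 1
    assert observed == expected


def test_duplicates_share_fragment_coordinates():
    lib = sim.simulate_library(sim.SimParams(n_pairs=2000, dup_rate=0.6, e0=0.001, seed=6))
    truth = lib.truth_frame()
    dups = truth[truth.duplicate_of >= 0]
    assert len(dups) > 0
    originals = truth.set_index("pair")
    for row in dups.itertuples(index=False):
        orig = originals.loc[row.duplicate_of]
        assert orig.frag_start == row.frag_start
        assert orig.frag_end == row.frag_end
        assert orig.strand == row.strand
        assert orig.duplicate_of == -1


def test_extreme_duplication_regime():
    """At dup_rate 0.975, deduplication leaves under 5% unique pairs and the
    measured fraction matches the parameter."""
    lib = sim.simulate_library(
        sim.SimParams(n_pairs=40_000, dup_rate=0.975, e0=0.0, seed=7)
    )
    unique, report = remove_duplicates(list(lib.pairs()))
    assert report.duplicate_fraction == pytest.approx(0.975, abs=0.005)
    assert len(unique) / 40_000 < 0.05


def test_short_fragments_give_short_reads():
    ref = sim.make_reference(50_000, 0.4, seed=3)
    lib = sim.simulate_library(
        sim.SimParams(
            n_pairs=300,
            reference=ref,
            frag_means=(60.0, 60.0),
            frag_sigma_log=0.1,
            e0=0.0,
            seed=8,
        )
    )
    flen = lib.frag_end - lib.frag_start
    for mate in ("R1", "R2"):
        lens = np.array([len(r.seq) for r in lib.read_records(mate)])
        assert np.array_equal(lens, np.minimum(flen, 100)[lib.tid])


def test_adna_mode_damages_only_c_at_5p_and_g_at_3p():
    lib = sim.simulate_library(
        sim.SimParams(
            n_pairs=3000,
            e0=0.0,
            damage=sim.DamageModel.adna(0.1, 10.0),
            seed=9,
        )
    )
    ev = lib.template_events
    assert len(ev) > 0
    # classify each event by which end it is closest to
    for row in ev.itertuples(index=False):
        assert (row.true, row.emitted) in {("C", "T"), ("G", "T")}
    assert set(ev.true) == {"C", "G"}


def test_damage_profile_expectation_at_read_ends():
    """With uniform type weights each substitution type's frequency at
    offset 0 is (a + e0)/3 of its reference base (the damage event picks one
    of three alternatives uniformly: conditional probability exactly 1/3 by
    enumeration), decaying to e0/3 in the interior."""
    # enumeration of the conditional draw
    dm = sim.DamageModel.formalin()
    for t in range(4):
        u = np.linspace(1e-6, 1 - 1e-6, 3001)
        alts = sim._conditional_alt(dm.weights5, np.full(u.shape, t, dtype=np.uint8), u)
        frac = np.bincount(alts, minlength=4) / len(u)
        assert frac[t] == 0.0
        for other in set(range(4)) - {t}:
            assert frac[other] == pytest.approx(1 / 3, abs=1e-3)

    a, e0 = 0.03, 0.003
    lib = sim.simulate_library(
        sim.SimParams(
            n_pairs=40_000, e0=e0, damage=sim.DamageModel.formalin(a, 8.0), seed=10
        )
    )
    prof = lib.mismatch_profile("R1")
    freq = prof.freq(0)
    target = (a + (1 - a) * e0) / 3
    for r in range(4):
        for c in range(4):
            if r == c:
                continue
            denom = prof.denoms[0, r, 0]
            sigma = np.sqrt(target * (1 - target) / denom)
            assert freq[r, c, 0] == pytest.approx(target, abs=4 * sigma)
            # interior plateau at the sequencing error floor
            sigma_i = np.sqrt((e0 / 3) / prof.denoms[0, r, 45])
            assert freq[r, c, 45] == pytest.approx(e0 / 3, abs=5 * sigma_i + 2e-4)


def test_end_to_end_trim_behaviour_of_presets():
    good = sim.simulate_library(sim.preset("good_specimen", n_pairs=25_000, seed=11))
    spec, _ = detect_trim(
        good.mismatch_profile("R1", unique_templates=True),
        good.mismatch_profile("R2", unique_templates=True),
    )
    assert min(spec.r1_5p, spec.r1_3p, spec.r2_5p, spec.r2_3p) > 0
    clean = sim.simulate_library(sim.preset("undamaged", n_pairs=25_000, seed=11))
    spec0, _ = detect_trim(
        clean.mismatch_profile("R1"), clean.mismatch_profile("R2")
    )
    assert spec0.is_zero()


def test_fresh_duplicate_errors_break_exact_duplicates(tmp_path):
    """With per-copy fresh sequencing errors, PCR copies are no longer
    guaranteed exact duplicates, so the exact-sequence estimator
    undercounts — while the truth-event bijection still holds."""
    params = sim.SimParams(
        n_pairs=3000, dup_rate=0.6, e0=0.01, duplicate_errors="fresh", seed=12
    )
    lib = sim.simulate_library(params)
    _, report = remove_duplicates(list(lib.pairs()))
    # (1-e0)^(2*read_len) ~ 0.13 of copies stay exact
    assert report.duplicate_fraction < 0.3
    sam = lib.write_truth_sam(tmp_path / "f.sam")
    observed = Counter()
    for aln in read_alignments(sam, lib.refset):
        mate = "R2" if aln.is_read2 else "R1"
        idx = int(aln.query_name[3:])
        obs, _ = extract_mismatches(aln, lib.refset)
        for o in obs:
            observed[(idx, mate, o.offset5, o.ref_base, o.read_base)] += 1
    expected = Counter()
    for row in lib.events_per_pair().itertuples(index=False):
        expected[(row.pair, row.mate, row.offset, row.true, row.emitted)] += 1
    assert observed == expected
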