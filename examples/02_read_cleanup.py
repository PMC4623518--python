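"""Hard trimming and the read-cleanup stages.

Applies a trim spec to a damaged library, then removes exact PCR
duplicates, filters low-quality pairs, and merges overlapping mates —
printing the per-stage accounting a QC report would show.
"""

from formalinqc import simulate as sim
from formalinqc.damage import TrimSpec
from formalinqc.readproc import apply_trim, merge_pairs, quality_filter, remove_duplicates

lib = sim.simulate_library(sim.preset("good_specimen", n_pairs=20_000, seed=2))
pairs = list(lib.pairs())

trimmed, t_rep = apply_trim(pairs, TrimSpec(6, 30, 17, 30), min_len=30)
print(f"trim:   kept {t_rep.kept_pairs}/{t_rep.total_pairs} pairs "
      f"(R1 -> 64 bp, R2 -> 53 bp for full-length reads)")

unique, d_rep = remove_duplicates(trimmed)
print(f"dedup:  {d_rep.unique_pairs} unique pairs, "
      f"duplicate fraction {d_rep.duplicate_fraction:.3f} (injected 0.64)")

clean, q_rep = quality_filter(unique)
print(f"qfilter: kept {q_rep.kept}/{q_rep.total}")

merged, kept_pairs, m_rep = merge_pairs(clean)
print(f"merge:  {m_rep.merged} overlapping pairs merged into single reads, "
      f"{m_rep.kept_pairs} pairs kept")
print("merged reads equal their template fragment (short inserts read through).")
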