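"""Empirical error rate before and after data-driven hard trimming.

The empirical error rate is mismatched aligned bases over total aligned
bases.  End damage inflates it; trimming the damaged offsets brings it
back toward the sequencing-error baseline.
"""

import tempfile
from pathlib import Path

from formalinqc import simulate as sim
from formalinqc.damage import detect_trim
from formalinqc.refmetrics import error_rate

params = sim.SimParams(
    n_pairs=30_000, e0=0.006, damage=sim.DamageModel.formalin(0.02, 8.0), seed=1
)
lib = sim.simulate_library(params)
spec, _ = detect_trim(
    lib.mismatch_profile("R1", unique_templates=True),
    lib.mismatch_profile("R2", unique_templates=True),
)

with tempfile.TemporaryDirectory() as tmp:
    pre = error_rate(lib.write_truth_sam(Path(tmp) / "pre.sam"), lib.refset, lib.ref_name)
    post_lib = lib.trimmed(spec)
    post = error_rate(
        post_lib.write_truth_sam(Path(tmp) / "post.sam"), lib.refset, lib.ref_name
    )

print(f"injected sequencing-error baseline e0: {100 * params.e0:.2f}%")
print(f"pre-trim  error rate: {100 * pre.rate:.2f}%  "
      f"({pre.mismatched_bases}/{pre.aligned_bases} bases)")
print(f"post-trim error rate: {100 * post.rate:.2f}%  (trims {spec})")
print("trimming removed the damage-inflated component; the remainder is the\n"
      "sequencing error floor plus a small residual damage tail.")
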