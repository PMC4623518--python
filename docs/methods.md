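# Methods

`formalinqc` implements the computational side of recovering usable sequence
from formalin-fixed, fluid-preserved museum specimens: profiling
base-misincorporation damage from alignments, deciding how hard to trim read
ends, cleaning the read set, and summarising what maps back to a reference.
Everything is testable against a built-in simulator that emulates the damage
phenomenology of such libraries, so no external data or aligner is needed.

## The damage signal and the mismatch profile

DNA from formalin-fixed specimens carries chemical base modifications
concentrated toward molecule ends. After alignment these appear as elevated
reference-mismatch frequencies near the 5′ and 3′ ends of reads, across
essentially all 12 ordered substitution types `ref→read` (unlike classic
ancient-DNA deamination, which is specifically C→T at 5′ ends and G→T at 3′
ends of double-stranded libraries; both modes are available in the
simulator).

For each mate (R1/R2) and each read end, the profile records, per offset
`i` (0-based distance from that end) and per substitution type `X→Y`:

* `count[X→Y][i]` — comparable aligned columns at offset `i` where reference
  base `X` was read as `Y`;
* `denom[X][i]` — comparable columns at offset `i` whose reference base is
  `X`.

The reported frequency is `count[X→Y][i] / denom[X][i]`: each type is
normalised by occurrences of **its own reference base**, the convention of
misincorporation plots in the degraded-DNA literature. It keeps a type's
baseline at `e/3` for sequencing error rate `e`, independent of base
composition, so transition and transversion curves are directly comparable.

Comparable columns are CIGAR M/=/X columns with both bases in `{A,C,G,T}`;
N columns count toward neither numerator nor denominator. Soft-clipped
bases are never compared but still occupy read offsets; hard clips are
ignored. Profiles are accumulated in **sequenced-read orientation**: for
reverse-strand alignments both bases are complemented and offsets flipped,
because the damage is an end-of-molecule effect and must not be averaged
out across strands. Only primary, mapped alignments with MAPQ ≥ 20
(configurable) contribute; ambiguous placements otherwise inflate apparent
mismatch rates. Reference bases come from the supplied FASTA; the MD tag is
used only when the FASTA lacks the contig, and disagreements resolve in
favour of the FASTA with a warning.

Profiles for trim detection are accumulated **after exact-duplicate
removal**. PCR copies replicate their template's damage, so they are
pseudo-replicates: leaving them in multiplies single-molecule damage events
by the duplicate cluster size and makes per-offset frequency estimates
heavy-tailed, which destabilises the trim rule below.

## The flatness rule for hard trimming

"Trim until the ends look like the interior" is formalised per
(mate, end), independently for the four combinations:

1. **Baseline.** For each type `t`, the median `m_t` and MAD `s_t` of its
   per-offset frequencies over a baseline window (default: the outer half of
   the profile, offsets `[max_offset/2, max_offset]` = `[25, 50]`), using
   only offsets whose denominator is at least `min_denom` (default 500).
   Per-type baselines matter because transition baselines exceed
   transversion baselines even in undamaged data.
2. **Flagging.** Offset `i < max_trim` (default 40) is flagged if any type
   exceeds `m_t + max(k_mad · 1.4826 · s_t, abs_floor)` with `k_mad = 3`
   and `abs_floor = 0.002`. The MAD term adapts to counting noise; the
   absolute floor declares per-type excesses under 0.2% biologically
   negligible regardless of significance.
3. **Trim length.** `1 +` the largest flagged offset (0 if none). Contiguity
   is deliberately not required — damage curves can dip under the threshold
   and re-exceed it nearer the end.

`max_trim` caps runaway trimming: profiles that are elevated everywhere
(as in failed libraries with unusable, unevenly damaged reads) hit the cap
and report non-convergence instead of silently consuming the reads.
If no baseline offset has enough data the detector raises an error naming
the end rather than guessing.

**Expected trim point.** For the simulator's formalin mode (uniform type
weights, amplitude `a`, decay `λ`), a damage event at offset `i` occurs
with probability `a·exp(−i/λ)` and lands on one of the three alternative
bases, so each type's excess frequency is `(a/3)·exp(−i/λ)`. Its
deterministic crossing of the floor is `λ·ln(a/(3·abs_floor))` ≈ 10 for
`a = 0.02, λ = 8`. Empirically the detected trims concentrate instead near
the **total**-excess crossing `λ·ln(a/abs_floor)` ≈ 19 at library sizes of
~50,000 pairs: between the two crossings the residual damage is below the
floor yet still lifts per-type frequencies over the threshold often enough
to be flagged, and flagging only extinguishes once the total excess decays
to the floor. `DamageModel.expected_trim_point` returns this empirical
crossing; the tests hold detected trims within ±4 bases of it. Undamaged
libraries sit far below the floor (the floor is ≈ 8 standard errors at
that size), so false trims are rare.

**Iteration.** Repeated profile→detect rounds run against the *original*
alignments with already-trimmed offsets masked and the remainder
re-indexed, rather than re-aligning trimmed reads. Masking is deterministic
and aligner-free; re-alignment after trimming can shift a handful of
marginal placements, which is irrelevant for profile statistics at these
scales. A pipeline that insists on realignment can feed the second-round
SAM back through the same entry point. A later round that trims so deep
that no baseline window survives stops the iteration with
`converged=False`.

## Read cleanup

* **Hard trim** — fixed counts per mate per end; any mate shorter than
  `min_len` (default 30) after trimming drops the whole pair. A trim
  exceeding the read length is a drop, not an error.
* **Duplicate removal** — key is `R1.seq + "|" + R2.seq`; qualities and
  names are ignored, first occurrence wins (order-stable, usable before
  alignment). Pairs, not individual reads, are the counting unit.
* **Quality filter** — drop a pair if either mate has mean Phred < 20
  (`≥` keeps) or more than 10% N.
* **Overlap merge** — reverse-complement R2, scan candidate overlaps from
  longest to shortest, accept the first with length ≥ 11 and mismatch
  fraction ≤ 10%; within the overlap each column takes the higher-quality
  base (R1 wins ties) and the max quality. Merged reads are emitted
  separately as unpaired data. The merged length always equals
  `len(R1) + len(R2) − overlap`.

Adapter trimming is out of scope; run a standard adapter trimmer upstream.

## Reference-based summaries

* **Empirical error rate** — mismatched / aligned comparable columns over a
  region, same column semantics as the profiles.
* **Coverage** — per-bin (default 10 kb) read counts (a read belongs to the
  bin of its leftmost aligned base, so bin counts sum to read count) and
  mean depth from full reference spans (M/=/X/D); genome-wide breadth
  (fraction of positions with depth ≥ 1) and mean depth.
* **Pileup / consensus** — per-position A/C/G/T tallies from M columns in
  reference orientation; deletions add no evidence, insertions are ignored.
  A site is called as the majority base when depth ≥ 3 and the majority
  fraction is ≥ 0.75, else `N`; exact ties give `N`. Sub-threshold sites
  emit `N` rather than the reference base to avoid reference bias in SNP
  counts. SNPs are called (non-N) sites differing from the reference;
  dissimilarity divides SNPs by called sites, the only denominator that is
  well-defined when part of the region is uncallable.
* **GC content** — (G+C)/(A+C+G+T), N excluded.
* **Contig filtering** — drop below 200 bp (default) and report N50, the
  largest `L` such that contigs ≥ `L` hold at least half the filtered
  length.

## The simulator

`simulate_library` emulates a short-fragment paired-end library from a
formalin-fixed specimen:

* **Fragments** — two-component lognormal mixture (means ~120 and ~240 bp,
  σ_log 0.25, equal weights — matching the double-peaked sizing traces of
  such libraries), truncated to ≥ 35 bp, uniform position and strand on the
  reference. Reads are the first `read_len` (default 100) bases of each
  fragment strand; fragments shorter than the read length yield
  fragment-length reads (no adapter read-through is simulated).
* **Damage** — per read end, position `i` from that end is substituted with
  probability `a·exp(−i/λ)`, 5′ and 3′ independently; the substitute is
  drawn from a 12-type weight table conditioned on the true base (rows with
  zero mass are immune — this is how adna mode restricts to C at 5′ and G
  at 3′). Formalin defaults: `a = 0.02`, `λ = 8`, uniform weights. The
  uniform draws are made before masking so that, at a fixed seed, raising
  `a` only adds events — trim detection is provably monotone in amplitude
  under coupled seeds.
* **Sequencing error** — i.i.d. rate `e0` to a uniformly random different
  base (default 0.002; 0.006 reproduces raw error rates typical of such
  runs).
* **Duplication** — a Binomial(n, dup_rate) number of emitted pairs are PCR
  copies, spread uniformly over templates (copy numbers ≈ 1 + Poisson);
  copies share the template's damage **and, by default, its sequencing
  errors**, i.e. they are exact sequence duplicates. Exact-sequence
  deduplication can only be calibrated against exact copies; per-copy
  fresh errors (`duplicate_errors="fresh"`) are available but make the
  exact-duplicate estimator an undercount by construction, as it also is
  on real data.
* **Sample divergence** — optional substitution rate vs the reference for
  consensus/SNP studies.
* **Truth** — fragment coordinates, duplicate lineage and every injected
  event are recorded; a truth SAM (all-M CIGARs, MAPQ 60, proper pair
  flags) lets the whole downstream pipeline run without an aligner.

Presets encode three study conditions: `good_specimen` (dup 0.64,
a = 0.02, λ = 8, e0 = 0.002 — a recently fixed specimen that sequences
usably), `failed_specimen` (dup 0.975, a = 0.08, λ = 15, e0 = 0.004 — an
old, low-input library dominated by duplicates and broad damage) and
`undamaged` (control).

**What the simulator does not model** — and hence what passing tests do not
show about real data: adapter contamination and read-through; quality-score
profiles (qualities are constant Q35) and quality-correlated errors;
indels; strand-asymmetric or sequence-context-dependent damage; molecule-
level damage shared between overlapping mate ends (damage is drawn per
read, so R1 and R2 of a short fragment can disagree in their overlap);
contaminant reads; mappability and alignment ambiguity (the truth SAM is
perfectly placed). Coverage at linear reference ends ramps down because
fragments cannot overhang; consensus tests therefore evaluate SNP counts
and the interior rather than literal end-to-end sequence equality.

## Problem sizes and tolerances

The test and acceptance workloads use 50,000 read pairs for profile/trim
and error-rate studies (20 seeds of 25,000 pairs for the zero-damage
specificity check), a 17 kb reference at ~50X for consensus studies, and a
1 Mb reference for GC recovery (binomial noise ≈ 0.0005, tested at ±0.002).
Statistical assertions use 3σ binomial bands (4σ for the many-comparison
per-type profile checks); trims are held within ±4 bases of the analytic
crossing; the post-trim error rate must fall below the pre-trim rate and
land within 20% of the injected baseline at the 0.006 baseline, where the
irreducible residual damage tail (≈ `2aλ·e^{−t/λ}`/kept-length per base) is
a small fraction of the floor.

## Known limitations

* The flatness rule needs well-powered profiles — roughly ≥ 3,000 columns
  per reference base per offset (≈ 20,000 reads per mate). Below that,
  count discreteness makes the absolute floor reachable by Poisson noise
  and the largest-flagged-offset rule overtrims; `min_denom` guards the
  baseline but deliberately does not second-guess flagged offsets.
* Detected trim lengths inherit the noise of a max statistic over ~480
  comparisons; at 50,000 pairs the spread is a few bases around the
  expected crossing, occasionally more.
* Exact-duplicate removal undercounts duplicates in the presence of
  sequencing errors (a property of the method, reproduced faithfully).
* Dissimilarity is reported over called sites only; with uneven coverage
  this denominator can differ from the region length.
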