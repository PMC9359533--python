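# Methods

## Problem setting

A plasmid library is built by replacing a 39-nt peptide CDS (the α-MSH
sequence in the bundled template) with a designed 54-nt randomized insert,
transforming the ligation into bacteria, and sequencing an amplicon that
spans the randomized region. The analysis takes the reads plus the observed
transformation-positive colony count and reports (a) how template-biased
the library is and (b) an estimate of its unique peptide-variant content.
The colony count is an external measurement (plate imaging); the pipeline
treats it as exact, and every estimate inherits its error proportionally.

## Region extraction

The randomized region is located by finding two constant anchors in the
read, in either orientation. Anchor matching is a semi-global edit-distance
search: substitutions and indels cost one edit each, a hit is accepted when
its distance is at most ⌊`anchor_max_error_rate` · anchor length⌋, and ties
are resolved by lowest distance, then leftmost start, then shortest span.
The default error rate is 0.1, the common default for adapter-trimming
tools; it is recorded in the config so runs are reproducible. The whole
anchor must lie inside the read — partial anchors at read boundaries are
rejected, which avoids extracting truncated regions from clipped reads.
When both orientations contain the anchor pair, the one with the smaller
total anchor edit distance wins (tie → forward).

The extracted region is the sequence strictly between the anchors:
`left_flank + insert + right_flank`. Retention filters run in a fixed
order so failure tallies are deterministic: empty region → ambiguous base
(any non-ACGT symbol; a codon containing N cannot be assigned a residue) →
flank mismatch (both flank trinucleotides must match exactly; flank
identity is a hard retention criterion, not something to correct) → length
not divisible by three.

Implementation note: the search is exact but cheap in the common case — an
exact substring scan first, then a pigeonhole k-mer screen (a match with ≤
*e* edits must contain one of *e*+1 contiguous anchor pieces exactly), and
only then the full dynamic program. The screen can only reject sequences
that provably contain no acceptable occurrence, so the semantics are those
of the dynamic program alone.

## Template-bias classification

Each retained region is aligned globally (Needleman–Wunsch, linear gap
penalty) against the template region — template insert plus both flanks,
45 nt. The classification consumes only the mismatch and gap-column counts
of the alignment, which are robust to the exact scoring scheme; the default
is match +1 / mismatch −1 / gap −1, configurable and logged.

A region is *insufficiently randomized* when mismatches < 10 AND gap
columns < 3. Two conventions here were genuinely open and are exposed as
switches, with the stricter readings as defaults: the bounds are strict
(`inclusive_bounds` flips both to ≤), and "gaps" are counted as gap
columns, not gap openings (`count_gap_openings` flips this; at a bound of
3 the distinction matters).

Traceback ties are broken with fixed precedence (diagonal > up > left), so
the reported mismatch/gap split is reproducible across runs and platforms.
Co-optimal alignments can split differently; counts are defined as those
of the deterministic traceback. A structural consequence worth noting: any
global alignment carries at least |len(query) − len(reference)| gap
columns, so a full-length 60-nt region can never be classified as
template-biased against the 45-nt reference — the classifier's behaviour
on full-length random inserts is geometric, not statistical.

Throughput: regions are deduplicated and equal-length groups share one
vectorized matrix fill; the per-region traceback is the only sequential
part. Batch and single-pair paths are the same recurrence and are
cross-checked in the tests.

## Peptide quantification

Regions translate in frame 0 with the standard genetic code, flank codons
included, so a stored peptide is: last secretion-signal residue + insert
peptide + terminal `*`. Internal stops are kept as `*` by default
(`truncate_at_stop` is available for users modelling expressed products;
short observed peptides in this kind of data are attributed to nucleotide
deletions, not nonsense codons, so truncation is not the default).

Variant identity is at the peptide level — synonymous reads are summed —
because the diversity estimate is a statement about peptide variants.
Classification happens per read; a variant's class is the majority label
of its supporting reads, ties called insufficiently randomized (the
conservative direction for a bias audit). Nucleotide-level collapse is
available for diagnostics. Peptide lengths in the length spectrum exclude
the terminal `*`, so a full-length designed insert scores 1 + 18 = 19.

## CPO diversity estimation

With read fractions *f₁…f_v* over retained reads and colony count *N꜀*,
CPOᵢ = fᵢ·N꜀ reconstructs the number of colonies variant *i* plausibly
occupies (colonies almost always carry a single plasmid variant). By
construction ΣCPO = N꜀ exactly; this identity forces the fraction
denominator to be the retained-read count, and it is asserted to 1e−9
relative tolerance on every run. The unique-variant estimate is

    N̂ = #{CPO ≥ 1} + round_half_away_from_zero(Σ_{CPO<1} CPO)

(the boundary CPO = 1 counts as confident). Half-away-from-zero rounding is
used because it is the everyday convention; the difference from banker's
rounding only matters at exact halves. The estimate never exceeds N꜀ + 1.
CPO is computed jointly over all variants and then partitioned by class, so
class-level sums add up to the library-level ones. Known limitations are
inherent: accuracy is bounded by colony-count accuracy, and plasmid
copy-number or colony-size differences distort fractions; no correction is
applied because none is well-determined by the available inputs.

## Composition statistics

For insert position *p*, residue frequencies are tallied over sequences
long enough to reach *p* (shorter peptides drop out of the denominator, so
rows stay normalized), weighted by read count by default (`by_variant`
weights each unique peptide once; variant-level claims are post-CPO, so
both views are offered and neither is canonical). The reference is the
uniform-NNN expectation — codon multiplicity / 64, computed by enumerating
all 64 codons (exact rational arithmetic available). Divergence is
summarized as total-variation distance, ½Σ|obs − exp| ∈ [0, 1], chosen as
the simplest bounded metric; a per-position chi-square goodness-of-fit
p-value is carried as a secondary descriptive column with no multiplicity
correction. Only plain NNN is modelled; NNK/NNS schemes would change only
the theoretical vector and are an extension hook, not a default.

## Synthetic libraries

The generator draws a ground-truth variant pool and then samples reads
from it; the two stages are separately seeded and fully deterministic.

* **Variant pool.** `n_template_variants` template-like inserts (the
  template CDS with i.i.d. substitutions at `template_mutation_rate`,
  default 0.02 — at 39 nt that is <1 expected substitution, so these reads
  classify as template-biased with probability ≥0.99) and the remainder
  uniform random inserts of the designed length. Random inserts carry
  length aberrations with probability `indel_aberration_rate`: whole-codon
  changes (±3/6/9 nt, deletion-biased 3:1) with probability 0.8 —
  producing shorter/longer peptides that survive filtering — and
  frame-breaking changes (±1/2 nt) otherwise, producing filter failures.
* **Abundances.** Log-normal with sigma `abundance_skew`, normalized per
  pool; the template pool's total mass is pinned to
  `template_bias_fraction`. Sigma ≈ 2.5 makes a handful of jackpot
  variants hold a majority of reads, emulating early-cycle PCR
  amplification bias phenomenologically; a mechanistic cycle-by-cycle PCR
  model is deliberately not attempted.
* **Reads.** `upstream_anchor + left_flank + insert + right_flank +
  downstream_anchor`, i.i.d. substitutions at 0.005/base over the whole
  read (anchors included) and a single-base insertion/deletion per
  homopolymer run ≥ 3 with probability 0.01 per run, emulating flow-based
  base-calling artefacts. About half the reads are emitted
  reverse-complemented. Qualities are constant placeholders — the pipeline
  never uses them, since upstream instrument software is assumed to have
  done quality filtering.

Three presets fix the study conditions: `wpa` (1 000 variants of which 8
template-like, bias 0.5, skew 2.5, aberration rate 0.05, 3 802 colonies),
`overflap` (5 000 variants, 1 template-like, bias 3·10⁻⁵, skew 1.0,
4 534 colonies) and `overflap-asym` (60 000 variants, no template pool,
skew 1.0, 4 865 colonies). Bias fractions and colony counts follow the
regimes the presets emulate; variant counts and skews are order-of-
magnitude choices consistent with the jackpot shares those regimes show
(top-variant dominance ~30–40 % under heavy bias, ≤5 % without it), and
the aberration rates are order-of-magnitude choices — no quantitative
indel/duplication rates are available to calibrate against.

What the generator does **not** emulate: position-dependent error
profiles, quality-score realism, chimeric reads, primer-dimer artefacts,
and any sequence-dependent amplification chemistry. Passing the simulation
tests therefore demonstrates correctness of the analysis logic under the
stated statistical structure, not robustness to every real-data artefact.

## Problem sizes and numerical choices

The test suite runs the bias-recovery check at 50 000 reads (binomial
sampling error ±0.2 % at share 0.5, comfortably inside the ±1 % assertion
given the ≤0.5 % attrition asymmetry from frame-breaking aberrations), the
variant-count recovery at 200 variants / 200 colonies / 100 000 error-free
reads (CPO per variant ≈ 1 ± 0.045, the regime where the two estimator
terms exchange mass and their sum stays within ±10 %), and the composition
check at 50 000 variants / 100 000 reads (per-position effective sample
≥ 50 000 gives TV fluctuation ≈ 0.008 ≪ the 0.02 bound). Alignment and
anchor kernels are verified against independent oracles — a top-down
recursion and an exhaustive path enumeration for Needleman–Wunsch, a
substring-enumeration scan (edlib distances) for the anchor search.

Degenerate inputs: an empty read set or a library with zero retained reads
produces a complete, zeroed summary rather than an error; empty regions,
ambiguous bases and frame breaks are counted per reason; classification of
a failed region is a hard programming error, not a data condition.
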