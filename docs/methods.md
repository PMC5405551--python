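# Methods

`circvar` quantifies heteroplasmy — the coexistence of several sequence
populations of a multi-copy circular genome, classically mitochondrial DNA —
from deep short-read sequencing aligned to a small circular reference. This
note documents the model, the defaults and the numerical choices, and what
the built-in simulator does and does not emulate.

## Pipeline model

The analysis consumes alignments of the same read set against two
orientations of one circular reference: the native linearisation and a copy
whose origin is rotated to the sequence midpoint (`s = floor(L/2)` exactly;
"approximately the centre" is made deterministic so results are
reproducible). A read spanning the native origin cannot align contiguously
in the native orientation but can in the shifted one, and vice versa; every
position is therefore well covered in at least one of the two runs. Each
orientation is processed independently (pileup → calling → per-position
rows); the shifted rows are re-coordinated through
`p_original = ((p_shifted − 1 + s) mod L) + 1` and the two row sets are
merged by keeping, per position, the row with the higher depth, all columns
travelling together. At equal depth the native-orientation row wins, because
reported numbering is native to it.

Coordinates are 1-based and closed everywhere. References may carry `N`
placeholders (the human rCRS has one at position 3107); these are stripped
before alignment and a coordinate map restores the conventional numbering in
every report. The stripping rule is generalised to any number of `N`s.

## Pileup

The pileup stage reproduces classic mpileup semantics with the published
operating point as defaults: minimum base quality `Q = 35`, minimum mapping
quality `q = 50`, adjustment coefficient `C = 50`. Reads below `q` contribute
nothing. Bases below `Q` are excluded from allele counts and from the
qualified depth but still count toward the raw depth (`Covmp`), which is the
depth a standard mpileup prints and the quantity the dual-run merge
compares; `QDepth` is the base-quality-filtered depth backing the counts.
Insertions anchor at the preceding aligned position and do not add to depth;
deletions are recorded once at their anchor and add to depth across their
span; soft clips are ignored; overlapping mates are counted independently
(the historical tool chain predates overlap de-duplication — a documented
caveat, since at extreme depth it slightly anti-conservatively doubles
fragment evidence).

The mapping-quality adjustment is the identity by default: the coefficient
is kept as a parameter, but simulated reads carry truthful mapping qualities
and `q = 50` is the operative filter. An optional hook
(`mismatch_downgrade_hook`) implements a heuristic downgrade,
`adj = round(mapq · (1 − m/n)^C)` for `m` mismatches over `n` aligned bases —
the identity at `m = 0` and monotone non-increasing in `m`.

Two indel normalisations happen at counting time:

* every indel is left-aligned against the reference (an insertion slides
  left while the anchor base equals its last inserted base; deletions
  likewise), so events inside repeat runs land on one canonical anchor;
* indel events of a single read that normalise to the same anchor are merged
  into one concatenated event. Aligners represent a two-base insertion
  inside a homopolymer in several edit-equivalent ways (one `2I`, or two
  split `1I`s); without merging, a `+AA` would fragment into spurious `+A`
  counts.

## Variant significance

At each position the best-supported alternate allele (SNV, insertion or
deletion; ties break deterministically — highest count, then SNV before
insertion before deletion, then lexicographic) is tested against a fixed
sequencing-error null with a one-sided Fisher's exact test on

```
[[reads1, reads2], [round(d·(1−e)), round(d·e)]],   d = reads1 + reads2
```

right (variant-enrichment) tail, with `e = 0.001` by default. Conditional on
margins this is a hypergeometric tail sum, and it is computed that way
(`scipy.stats.hypergeom.sf`, vectorised across positions); the test suite
verifies agreement with an exact big-integer enumeration to 1e-12 on every
table with depth ≤ 200. `reads2 = 0` returns p = 1. A variant is reported
when frequency ≥ `min_var_freq` (0.1%), support ≥ `min_reads2` (2, a guard
against singleton artifacts) and p ≤ 0.001. The upstream tool this stage
reconstructs does not publish its internals; the construction above is
therefore documented and parameterised rather than claimed identical.

Frequency is `reads2 / (reads1 + reads2)`. For an indel candidate the
reference support is corrected twice before this ratio is formed:

* indel carriers also present a matching anchor base, so the candidate's own
  support is subtracted from the anchor's reference count (otherwise an 84%
  insertion would report ~46%);
* reads whose alignment *ends* inside the event's ambiguity window — the
  anchor plus the reference repeat run the event extends (for `+AA` before
  `AAAAAAAA`, eleven positions) — cannot distinguish the two alleles and are
  removed from reference support. Without this, read truncation alone caps a
  homoplasmic homopolymer insertion at ~92%.

The strand-bias filter (`Fail` when one strand carries > 90% of the variant
support, `NA` without support) annotates calls but never removes them; it is
reported as a column so consumers can promote it to a hard filter.

## Coverage flags, masking, consensus

Relative coverage is `100 · Covmp / mean(Covmp)` with the mean over **all**
reference positions including zero-coverage ones. Flags: `GOOD` ≥ 10%,
`WARNING` ≥ 1%, `EXCLUDE` < 1%, boundaries inclusive at the lower edge of
each class (exactly 10% is `GOOD`; the published thresholds state no
inclusivity, so the choice is documented here). `EXCLUDE` positions are
masked: consensus symbol `N`, frequency forced to 0, no variant reported.

The consensus FASTA is substitution-only by default — one symbol per
reference position (major allele, or `N`), keeping coordinates stable for
downstream haplogroup tools; an opt-in flag applies > 50% indels.

## Heteroplasmy classes and pedigree screens

Variant frequencies partition into homoplasmic (> 98%, strictly),
high-frequency heteroplasmy (10–98%) and low-frequency heteroplasmy (1–10%).
Exactly 98% is high; exactly 10% is high (the prose bounds "between 10 and
98" and "between 1 and 10" leave 10 unassigned; assigning it upward makes
the classes tile the axis). SNVs below 1% and indels below 10% are not
reported — floors motivated by the error structure of the assay (indels in
homopolymer contexts carry a false-positive background an order of magnitude
above SNVs). Variants on non-`GOOD` positions are suppressed at the
reporting layer by default and restorable with a flag; the calls themselves
are never deleted.

The pedigree screens operate on reported variants: father-specific variants
(reported in a father, absent from the corresponding mother) are tabulated
with their frequency in every offspring; the mothers' variants likewise; a
child variant reported in neither parent is listed as de novo. The sharing
matrix records the measured frequency of each variant allele in every
sample, reported or not, so near-threshold sharing remains visible.

## Simulator

The generator emulates the benchmark design the pipeline is meant to be
judged by: two haplotypes of one circular genome mixed at known ratios.

Defaults — these are the study conditions, not tuning knobs:

| parameter | default | rationale |
| --- | --- | --- |
| genome length | 16,569 bp | human mtDNA scale |
| SNV set | 88 random distinct positions | the two-strain distinguishing set |
| insertions | `+G`; `+AA` before a planted 8-A homopolymer | the published indel pair, including the hard homopolymer context |
| ratios | 0, 0.4, 0.8, 1.6, 3.2, 6.25, 12.5, 25, 50, 75, 90, 100 % | twelve ratios; a two-fold series through the published sensitivity points (0.4/0.8/1.6) plus anchors — the exact twelve are not enumerated in the source, so this grid is an explicit stand-in |
| coverage | 3,000X | published mean depth |
| reads | 2×150, adjacent mates, 300 bp fragments | published chemistry; fixed fragment length keeps each pair within 300 contiguous circular bases |
| substitution error | 0.1% /base, phred 40 | typical Illumina miscall floor; errors keep full quality because they model miscalls, not low-confidence calls |
| indel error | 0.01% /base, single-base | rare polymerase slippage |
| mapping quality | 60 | truthful simulated mappings |

Amplification noise (the rolling-circle error floor that motivates the
1%/10% reporting thresholds on real data) is **not** added by default; an
`rca_noise` term can add extra substitution error for sensitivity studies.
Keeping the default model clean makes benchmark results interpretable as
pipeline properties rather than assay properties.

Fragment starts are uniform on the circle of the sampled haplotype; each
fragment is haplotype B with probability `ratio/100`. Reads are emitted in
every orientation where their mapping is contiguous — most reads appear in
both SAMs, origin-spanning reads in exactly one. Reads with non-trivial
alignments (overlapping an engineered insertion, carrying an injected indel
error, or wrapping the haplotype origin through an inserted region) are
realigned against the reference with edlib (infix mode, full path), so their
CIGARs exhibit the same representational ambiguity a production aligner
produces — this is what exercises the left-alignment and event-merging
machinery above. All randomness flows from one seeded generator; identical
seeds give byte-identical FASTQ/SAM.

What the simulator does **not** emulate: quality-score profiles and
position-dependent error rates, GC/tagmentation coverage bias, nuclear
pseudogene (NUMT) contamination, chimeric reads, and amplification noise by
default. Passing benchmarks therefore demonstrate correctness of the
analysis under idealised sequencing; they bound, but do not measure,
performance on real libraries.

## Benchmark metrics

Measured frequency at a truth position is the row frequency when the row's
best-supported allele equals the engineered one (irrespective of the
significance filter — sensitivity and accuracy are deliberately decoupled),
else 0. Expected frequencies are calibrated from the measured 50/50 run,
`expected(r) = r · f₅₀/50`, absorbing mixing offsets exactly as the published
procedure does. Accuracy is the Pearson correlation and OLS slope between
calibrated expected and mean measured frequency across ratios; sensitivity
is the per-ratio fraction of truth SNVs passing all filters; specificity is
the count of passing SNV calls at non-truth positions; the per-variant
covariate `variant_density` counts truth variants in a circular 300 bp
window (2 × read length) centred on each variant, self included.

## Problem sizes used by the test suite and acceptance script

The acceptance script and the study-scale tests run the full design
(16,569 bp, 88 SNVs + 2 insertions, twelve ratios, 3,000X ≈ 166k read pairs
per mixture, ≈ 2M pairs overall) — a few minutes on one core. Unit tests use
1.2–6 kb genomes at 80–1,000X, which the same code paths cover; the
specificity property is additionally checked across five further seeds at
reduced scale (6 kb, 1,000X, no engineered variants).

## Known limitations

* Overlapping mates are double-counted (documented above); p-values at
  positions covered by both mates of many fragments are slightly
  anti-conservative.
* Left-alignment stops at position 1 of the working orientation; an indel
  inside a repeat run that itself spans the origin may normalise to
  different anchors in the two orientations. The dual merge keeps one row
  per position, so counts are consistent, but such events are best read from
  the orientation where the run is contiguous.
* The significance null uses a fixed error rate `e` rather than per-base
  qualities; with uniform phred-40 data the two coincide in practice.
* Single-orientation mode (`--no-shifted`) is supported but degraded by
  design: positions within a fragment length of the origin lose coverage
  and are flagged, exactly the failure mode the dual-reference design
  removes.
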