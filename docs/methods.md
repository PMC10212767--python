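# Methods

## Model

An antisense RNA, for this package, is a transcription unit on the strand
opposite a known (sense) transcript, overlapping it in genomic space. The
search space is a representative transcriptome — one isoform per gene, the
one with the longest CDS (ties broken by longer transcript, then
lexicographically smallest transcript id, so output is deterministic) —
and all statistics are computed in transcript coordinates (0-based,
half-open; on a "−" gene, transcript coordinate 0 is the rightmost genomic
base). Stranded alignments to the transcript sequences are labelled
`sense` (forward) or `antisense` (reverse complement).

The core quantity is the strand-by-region 2×2 table of a window against
the rest of its transcript, summarised by **logASR**, the log2 odds ratio
after adding a Haldane–Anscombe pseudocount c = 0.5 to all four cells.
The pseudocount is applied always, not only to zero cells, so the
estimate and its standard error stay mutually consistent, and every
logASR is finite. The significance test is the Wald test of that log odds
ratio, z = lnOR/√(Σ 1/(cell+c)). With a single binary predictor the
logistic-regression MLE coefficient *is* the sample log odds ratio, so
this closed form is exactly the "logistic regression of strand on window
membership" formulation — it is fast, reproducible, and agrees with the
two-sided Fisher exact test in ≥ 95% of significance calls over an
exhaustive grid of tables with margins ≤ 200 (the exact test is kept in
the test suite as an independent oracle, never as the implementation).
The all-zero table gives z = 0, p = 1. Multiple testing is controlled by
Benjamini–Hochberg throughout.

logASR is reported in log2 (thresholds 0.5 and 1.0 live on that scale),
and p-values are floored at the smallest positive double so the (0, 1]
contract holds even for enormous effects.

## Pipeline stages and parameters

**Scan.** Windows of `width` = 500 nt advance in `step` = 250 nt; tiling
stops at the first window reaching the transcript end, a terminal window
narrower than the step is dropped, and transcripts shorter than the width
get one full-length window. Reads are assigned to windows by their
biological 5′ end (start for sense reads, end−1 for antisense reads) so
each read contributes to exactly one cell per strand. Thresholds are
strict: logASR > 0.5 and q < 0.01. Significant windows that overlap or
are book-ended merge per transcript; merged loci are refined to the span
of all antisense reads *overlapping* the merged interval (refinement may
extend beyond the merged bounds; clipped to the transcript), then
re-scored with the refined interval as the window. The refined loci form
their own BH family — "recalculated" FDR is read as a fresh family rather
than pooling with the window-level tests. The initial window thresholds
are applied before merging and the same thresholds again after
refinement.

**Background loci** are merged windows with logASR ≤ 0 and q > 0.5. The
two inequalities reconcile two near-equivalent published phrasings
("approximately 0" vs "< 0"); both cutoffs are configurable. Optional
down-sampling to `n` loci uses a seeded uniform draw (merge first, then
sample).

**ChIP filter.** A sample supports a locus when ≥ 1 bp of one of its
peaks overlaps the union of the locus's genomic blocks and the
`upstream_bp` = 2000 window 5′ of the antisense unit on *its own* strand
(left of the unit when the antisense strand is "+", right when "−").
2 kb is a promoter-proximal scale for POLR2A; no published value exists
for this window, so it is exposed as a flag. Peaks are unstranded.
Quantiles use numpy's linear interpolation between order statistics — the
IQR is convention-sensitive, so the convention is pinned here. The pass
rule is count ≥ median + IQR ("at least one IQR above the median"). A
degenerate null (IQR = 0) passes everything at or above the median and is
logged loudly rather than raised, since the filter is a screen, not a
gate that should abort a run.

**RNA-seq confirmation** reuses the identical counting and statistic code
path with the whole refined locus as the window (windowed re-testing
would fragment the locus for no inferential gain), and BH within the
ChIP-passing set only. Final thresholds: logASR > 1.0, q < 10⁻⁵, strict.
One confirmation library is scored; pooling of libraries is the caller's
responsibility. Overlap classification uses the locus's own genomic
strand (the antisense unit is itself a transcript on the strand opposite
its host) against reference transcript spans; biotypes containing
"antisense" or "pseudogene" take precedence over other overlaps, and a
reference without biotype attributes downgrades all overlaps to
`annotated_other` with a warning.

**Condition comparison** (`compare_conditions`) is deliberately
screen-grade: a 2×2 odds ratio of in-locus antisense reads against the
transcript's remaining reads between two libraries, labelled as such in
its output. It has no dispersion model and is not a substitute for a
replicate-aware differential-expression method.

**Poly(A) usage.** For a (proximal, distal) site pair the per-condition
ratio is (distal+c)/(proximal+c) and the usage shift is the pseudocounted
log2 odds ratio between conditions — identically log2(ratio_B) −
log2(ratio_A) — with the shared Wald test. Multi-site genes are screened
pairwise (`each-vs-proximal` or `adjacent-pairs`) with BH across all
pairs of the run. 3′ end-seq reads map to a site when their 3′ terminus
falls within ±25 nt of the annotated position (nearest site wins, ties to
the proximal one). Replicate libraries are **summed within condition**
before testing; replicate-to-replicate variability is not modelled, a
known limitation that makes p-values optimistic when replicates disagree.

## Synthetic data

The generators produce every input the pipeline consumes, with the
structure the method assumes and nothing more: no sequencing-error,
quality, fragment-length or positional-bias modelling, fixed 50-nt reads
(variable lengths add nothing to the statistics under test). Each
generator draws from `default_rng([seed, offset])` with a fixed per-stream
offset, so any subset regenerates identically.

- **Transcriptome**: single-isoform genes, 1–5 exons, lengths uniform on
  1500–4000 nt, laid out without overlap on ten synthetic chromosomes.
- **Reads**: Poisson(2000) reads per transcript with uniform 5′
  positions; each read flips to antisense with probability 0.05 (a
  realistic stranded bleed-through rate, and deep enough coverage that
  the Wald approximation is well calibrated — the null p < 0.05 fraction
  sits within Monte-Carlo error of 0.05). Inside a declared unit the
  antisense:sense *odds* are multiplied by 2^enrichment, so the declared
  enrichment is exactly the expected in/out odds ratio that logASR
  estimates. Default benchmark: 30 units of 500–1000 nt at enrichment
  2.5 among 200 genes, in both GRO-seq and RNA-seq libraries.
- **ChIP**: 67 samples; each emits a 300-bp peak (±100 bp jitter) centred
  500 bp upstream (strand-aware) of each true unit with probability 0.8
  and of each background locus with probability 0.1.
- **APA**: multinomial counts per condition; default usage 0.7/0.3 vs
  0.4/0.6 (a log2 3.5 ≈ 1.81 shift), two replicate libraries of 500 reads
  per condition, summed before testing to mirror how duplicate 3′
  end-seq libraries are analysed.

What passing these simulations does *not* show about real data: no
positional bias, no over-dispersion between ChIP samples (real peak
presence is correlated across cell lines), no mappability artefacts, and
antisense units are uniform in density rather than promoter-shaped.

## Numerical and benchmark notes

- Refined-boundary accuracy is quoted as the **mean** absolute deviation
  of refined bounds from the true unit bounds over recovered units
  (~160 nt at default settings). Individual boundaries carry irreducible
  window-grid jitter (up to one 250-nt step when a partially overlapping
  neighbouring window is also significant) plus read-length extension, so
  a strict per-unit ±250 guarantee is not attainable by construction.
- The ChIP median+IQR rule sits near the ~86th percentile of a
  Binom(67, 0.1) background, so with iid background presence about
  8–15% of background loci exceed the threshold. The filter's value is
  the enormous margin of true promoters (mean count ≈ 54 vs threshold
  ≈ 10), not a calibrated 5% false-pass rate.
- A handful of true units can fail the ChIP stage when the simulated
  promoter peak falls into a host-gene intron: locus blocks are exonic
  and the upstream window extends from the block edge, so an intronic
  peak is invisible. This mirrors a genuine failure mode of
  exon-projected antisense annotations.
- Benchmark sizes (20 end-to-end replicates of the 200-gene study, 2,000
  null windows, 100 APA replicates, the step-10 grid for the exact-test
  comparison) keep a full desk-scale validation run in the
  few-minutes range on one CPU while leaving Monte-Carlo error well below
  the margins being tested.
- All tabular intermediates are TSV; loci carry their genomic projection
  as `start-end[,start-end...]` block strings, written to BED6/BED12 with
  the BED score column round(min(1000, 100·|logASR|)) — display only,
  never computed with.
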