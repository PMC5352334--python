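# Methods

## Model

`msikit` treats microsatellite instability as a property of a tumor-normal
*pair*, not of individual loci. The matched normal acts as an
error-correcting baseline: PCR stutter, alignment artifacts and
locus-specific quirks affect both samples similarly, so the distance between
the two samples' repeat-length distributions isolates somatic change.
Averaging that distance over many loci invokes the law of large numbers —
single noisy loci cannot dominate the aggregate score.

### Per-locus distance

For a locus with motif `m` and per-sample histograms of read-supported
repeat counts, both histograms are normalized to fractions (removing any
depth difference between the samples) and compared with an L1 ("stepwise")
distance over the union of observed lengths:

    d = Σ_{r ∈ R_T ∪ R_N} |T_r − N_r|,   0 ≤ d ≤ 2

`d = 0` iff the distributions are identical; `d = 2` iff they share no
repeat length. The summation iterates lengths in sorted order, which makes
the floating-point result deterministic and exactly symmetric in its
arguments. The pair score is the arithmetic mean of `d` over passing loci
(discarded loci are excluded from numerator and denominator), and the MSI
call is positive iff the score strictly exceeds the threshold.

### Read pipeline

Per locus and sample, reads are processed in a fixed filter order, and each
read records only its first failure:

1. **spanning** — the aligned reference span must contain
   `[start − f, end + f)` with flank `f = 1`; unmapped, secondary,
   supplementary and duplicate-flagged reads are excluded outright;
2. **length** — reads shorter than `min_read_length` are dropped;
3. **read quality** — mean Phred over the read below `min_read_quality`
   drops the read (boundary inclusive: exactly the threshold passes);
4. **motif location** — the locus start is projected through the alignment
   into read coordinates, then adjusted by exact match within ±2 bases; the
   found copy is walked left to the run's first whole copy;
5. **truncation** — if the run, including a partial motif copy continuing
   the period, reaches either end of the read, the true length is
   unknowable and the read is dropped;
6. **locus quality** — mean Phred over the run below `min_locus_quality`
   drops the read.

Repeat counting is exact string matching of whole motif copies on the
read's base sequence. Indels inside the run are the very signal being
measured, so the CIGAR is deliberately not used to "repair" the run; a
sequencing mismatch inside the run truncates the count for that read, which
the outlier filter and the normal baseline then absorb. Partial trailing
copies do not count (integer copy numbers only).

### Distribution QC

Outlier repeat lengths are removed in a single pass: with support-weighted
mean μ and support-weighted *population* (n-denominator) standard deviation
σ, a length `r` is discarded when `|r − μ| > k·σ` (default `k = 3`). The
weighted form treats the distribution, not the set of distinct lengths, as
the object; the population denominator keeps σ deterministic. One pass
only — iterating to convergence would change the statistic. With a single
observed length σ = 0 and nothing is removed. After stripping, a locus
needs `min_locus_coverage` supporting reads in *both* samples; because
coverage is checked after outlier removal, stripping can disqualify a
locus. A locus empty in either sample is discarded as `no_support`.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `min_read_length` | 35 | bases | whole-exome guidance; shorter reads rarely span a run plus anchors |
| `min_read_quality` | 20 | mean Phred | standard Q20 read-level floor |
| `min_locus_quality` | 25 | mean Phred | the run itself must be called confidently |
| `min_locus_coverage` | 20 | reads/sample | enough support for a stable histogram |
| `outlier_sd` | 3.0 | SD multiples | conventional 3-sigma outlier rule |
| `threshold` | 0.4 | score units | aggregate score above which a pair is MSI-positive |
| flank `f` | 1 | bases | an anchor base each side guards against edge-truncated runs |
| start search window | ±2 | bases | absorbs projection error from indels near the run |
| scanner `min_repeats` | 6 (unit 1), 3 (units 2–6) | copies | homopolymer panels conventionally start longer; shorter thresholds flood the catalog |
| realignment window | ±1 | bases | exactly the 0/1-based indexing ambiguity; larger shifts are data errors |

All QC thresholds are CLI-overridable (`msikit score --help`).

## Locus ranking

Across a labeled cohort, a locus's discriminative power is the difference
of averages `a = mean(d | MSI-H) − mean(d | MSS)` over pairs in which the
locus passed coverage QC, downweighted by squared coverage proportion:
`l = a·c²` with `c` = covering pairs / total pairs. Missing distances are
excluded from the means rather than imputed as 0 (absence of coverage is
not evidence of stability). Loci covered in only one label group have
undefined `a` and rank last. Ties in `l` break by higher `c`, then genomic
order, for determinism. Ranking uses only the distance statistic — the
per-locus-accuracy variant used by per-locus callers is out of scope.

## Evaluation

Calls (`score > threshold`) are tallied against gold labels;
sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
error rate = incorrect/total, accuracy = 1 − error rate. Metrics with a
zero denominator are reported as undefined, never as 0. Sensitivity and
specificity carry 95% Wilson score intervals *with continuity correction*
(closed-form Newcombe bounds, clipped to [0, 1]; lower bound 0 at 0
successes, upper bound 1 at n successes). Threshold sweeps evaluate an
inclusive linear grid (default 600 points over [0.001, 0.6]) and report the
accuracy-maximizing threshold, smallest first on ties. Reported
percentages round to one decimal.

## Synthetic data

The simulator states a fully known world so that exact recovery is
testable:

- **Reference**: seeded random background with motif runs planted at fixed
  coordinates; the bases flanking each run are drawn to break the period,
  so planted runs are exactly maximal, and the background is re-rolled
  locally until a scan finds nothing but the planted loci.
- **Reads**: per locus and sample, repeat counts are drawn from the
  specified categorical distribution (default depth 50 reads per sample,
  read length 100, Phred 30); each read is reference flank + `motif ×
  drawn` + reference flank, written pre-aligned with a CIGAR encoding the
  insertion or deletion versus the reference run. Tumor distributions may
  be an explicit categorical, or `None` to mirror the normal read-for-read
  (an exactly stable pair). Base errors (default rate 0) are injected
  outside the run only, so drawn histograms remain exactly recoverable; an
  error-in-run mode is available by widening the protected interval in
  code for robustness experiments.

What the simulator does *not* emulate: PCR stutter, capture/GC bias,
fragment-size distributions, mapping ambiguity, contamination, or partial
tumor purity. A green end-to-end test therefore establishes that the
pipeline measures repeat-length distributions correctly and reproduces the
analytic score endpoints — not that the 0.4 threshold is optimal on real
tumors, which was established on large patient cohorts out of reach of
this test suite.

Writing reads pre-aligned (rather than through an external aligner) removes
aligner dependence; the caller consumes any coordinate-sorted indexed BAM.

## Numerical choices

- Distances summed in sorted-length order; aggregate is a plain mean.
- Scores at exactly the threshold are negative calls (strict inequality).
- File outputs round to 6 decimals; full precision is kept internally.
- Per-locus computations are independent; locus order never changes any
  output value.
- Realignment tries offsets {0, −1, +1} in that order and then extends the
  run to maximality in the reference, so under-annotated BED entries are
  corrected before truncation checks.

## Known limitations

- Exact in-run matching means high in-run error rates bias counts downward
  for long runs; the matched normal absorbs most, but not all, of this.
- No mate-pair rescue: only individually spanning reads contribute, so very
  long loci lose coverage quadratically with run length.
- Two-way calling only (MSI-positive/negative); no MSI-L band.
- The scanner reports forward-strand motifs without reverse-complement
  canonicalization, matching how reference-aligned reads observe loci.
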