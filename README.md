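# msikit

Microsatellite instability (MSI) calling from paired tumor-normal
next-generation sequencing alignments.

MSI is a somatic phenotype of mismatch-repair-deficient tumors: the lengths
of short tandem repeats (microsatellites, 1–6 bp motifs) drift because
replication slippage goes uncorrected. Detecting MSI matters clinically —
MSI-high tumors respond to immune checkpoint inhibition — and sequencing
data already collected for other purposes can be reused to call it.
`msikit` is for bioinformaticians who have coordinate-sorted, indexed BAM
files for a tumor and its matched normal and want a single, continuously
valued instability score plus an MSI-positive / MSI-negative call.

## The statistic

At each target microsatellite locus, reads that fully span the repeat run
are extracted from each sample, quality-filtered, and the number of
consecutive motif copies in each read is counted, giving per-sample
repeat-length histograms. After outlier stripping (lengths beyond 3 SD of
the support-weighted mean) and a coverage check, each histogram is
normalized to fractions and the locus is scored with a stepwise (L1)
distance:

    d = Σ_{r ∈ R_T ∪ R_N} | T_r − N_r |

where `T_r` and `N_r` are the tumor and normal fractions of reads
supporting repeat length `r`, and the union runs over lengths observed in
either sample. `d` is 0.0 when the two distributions are identical and 2.0
when they share no length. The pair's **aggregate instability score** is
the mean of `d` over quality-passing loci; the pair is called
**MSI-positive when the score exceeds 0.4** (strict).

Companion modules provide:

- a microsatellite scanner that discovers maximal primitive-motif runs in a
  reference genome and writes the annotated 6-column BED (`(AC)12`-style
  name field) the caller consumes;
- cohort locus ranking by the difference of averages `a` (mean `d` in
  MSI-H pairs minus mean `d` in MSS pairs) weighted by squared coverage,
  `l = a·c²`, with top-N BED panel export;
- evaluation utilities: confusion metrics, continuity-corrected Wilson 95%
  confidence intervals, and threshold sweeps;
- a seeded simulator producing references with planted repeats and paired
  normal/tumor BAMs drawn from configurable repeat-length distributions.

## Worked example

Simulate a six-locus pair whose tumor reads all carry deletions of three
motif copies, then score it:

```sh
msikit simulate --seed 7 --output demo --n-loci 6 --shift 3
msikit score --normal demo/normal.bam --tumor demo/tumor.bam \
             --bedfile demo/truth_loci.bed --genome demo/reference.fa \
             --output demo/pair
```

prints

```
Average_Difference      2.000000
Call    MSI-positive
Loci_Pass       6       Loci_Discarded  0
```

and `demo/pair.loci.tsv` begins

```
locus   motif   status  normal_counts   tumor_counts    difference
chr1:100-112    (A)12   pass    12:50   9:50    2.000000
chr1:312-328    (AC)8   pass    8:50    5:50    2.000000
chr1:528-543    (AAT)5  pass    5:50    2:50    2.000000
```

Every locus has 50 normal reads at the reference repeat count and 50 tumor
reads three copies shorter, so each per-locus distance is the maximal 2.0
(disjoint distributions), the aggregate is 2.0, and the pair is called
MSI-positive at the 0.4 threshold. Re-running with `--shift 0` makes the
tumor mirror the normal read-for-read and yields an aggregate of exactly
0.0, MSI-negative.

Real tumors sit between these extremes: partial tumor-cell fractions and
locus-to-locus variability produce intermediate scores, which is why the
call uses a threshold rather than the endpoints.

## Acceptance script

`scripts/acceptance.py` re-derives the two analytic score-range endpoints
from scratch: it simulates one fully disjoint and one exactly stable
10-locus pair (depth 50, error-free reads, seeded), runs the complete
pipeline on the BAMs, and writes the two aggregate scores as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model, parameter defaults, and the
simulator's scope and limitations.
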