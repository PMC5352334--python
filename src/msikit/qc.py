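"""Per-locus distribution post-processing: outlier stripping and coverage QC.

Outlier removal drops repeat lengths far from the distribution's mean before
scoring, so that a handful of aberrant reads (mismapping, chimeras) cannot
dominate the locus distance.  The mean and standard deviation are weighted
by read support and use the population (n-denominator) form; removal is a
single pass.  Tumor and normal are evaluated separately.  After stripping,
a locus must retain a minimum number of supporting reads in *both* samples
or it is discarded.
"""

from __future__ import annotations

import numpy as np

from .reads import RepeatDistribution


def remove_outliers(dist: RepeatDistribution, outlier_sd: float = 3.0) -> RepeatDistribution:
    """Drop repeat lengths beyond ``outlier_sd`` weighted SDs from the weighted mean.

    A length ``r`` is removed when ``|r - mu| > outlier_sd * sigma``.  With a
    single observed length sigma is 0 and nothing is removed.  Empty input is
    returned empty.
    """
    if outlier_sd <= 0:
        raise ValueError("outlier_sd must be positive")
    if not dist.counts:
        return RepeatDistribution(counts={}, sample_role=dist.sample_role)
    lengths = np.array(list(dist.counts.keys()), dtype=float)
    support = np.array(list(dist.counts.values()), dtype=float)
    mu = float(np.average(lengths, weights=support))
    sigma = float(np.sqrt(np.average((lengths - mu) ** 2, weights=support)))
    kept = {
        r: c
        for r, c in dist.counts.items()
        if abs(r - mu) <= outlier_sd * sigma
    }
    return RepeatDistribution(counts=kept, sample_role=dist.sample_role)


def locus_passes_coverage(
    normal: RepeatDistribution, tumor: RepeatDistribution, min_locus_coverage: int
) -> bool:
    """True iff both samples retain at least ``min_locus_coverage`` reads post-QC."""
    return normal.total >= min_locus_coverage and tumor.total >= min_locus_coverage
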