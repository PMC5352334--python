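"""Per-locus stepwise distance, pair-level aggregate instability score, and the MSI call.

Each quality-passing locus contributes a distance

    d = sum over r in R_T union R_N of |T_r - N_r|

where ``T_r`` and ``N_r`` are the tumor's and normal's normalized (fractional)
read support for repeat length ``r``, and the union runs over lengths observed
in either sample.  ``d`` ranges from 0.0 (identical length distributions,
entirely stable) to 2.0 (no shared length, entirely unstable).  The pair's
instability score is the arithmetic mean of ``d`` over passing loci; a pair is
called MSI-positive when the score strictly exceeds the threshold
(default 0.4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pysam

from .loci import MicrosatelliteLocus
from .qc import locus_passes_coverage, remove_outliers
from .reads import QualityConfig, RepeatDistribution, locus_distribution

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.4


class NoEvaluableLociError(Exception):
    """Raised when every locus was discarded and no aggregate score exists."""


@dataclass(frozen=True)
class NormalizedDistribution:
    """Repeat-length fractions of one sample at one locus; sums to 1."""

    fractions: dict[int, float]


@dataclass
class LocusResult:
    locus: MicrosatelliteLocus
    status: str  # "pass" or "discarded:<reason>"
    normal_counts: dict[int, int] = field(default_factory=dict)
    tumor_counts: dict[int, int] = field(default_factory=dict)
    normal_norm: NormalizedDistribution | None = None
    tumor_norm: NormalizedDistribution | None = None
    distance: float | None = None

    @property
    def passed(self) -> bool:
        return self.status == "pass"


@dataclass
class PairResult:
    locus_results: list[LocusResult]
    aggregate: float
    threshold: float
    call: str  # "MSI-positive" | "MSI-negative"

    @property
    def n_pass(self) -> int:
        return sum(1 for r in self.locus_results if r.passed)

    @property
    def n_discarded(self) -> int:
        return len(self.locus_results) - self.n_pass


def normalize(dist: RepeatDistribution) -> NormalizedDistribution:
    """Scale supporting-read counts to fractions of the sample's total."""
    total = dist.total
    if total <= 0:
        raise ValueError("cannot normalize an empty distribution")
    return NormalizedDistribution({r: c / total for r, c in dist.counts.items()})


def stepwise_difference(
    tumor: NormalizedDistribution, normal: NormalizedDistribution
) -> float:
    """L1 distance between the two fraction maps over the union of lengths."""
    # summed in sorted length order so the result is deterministic and
    # bitwise symmetric in its arguments
    d = 0.0
    for r in sorted(tumor.fractions.keys() | normal.fractions.keys()):
        d += abs(tumor.fractions.get(r, 0.0) - normal.fractions.get(r, 0.0))
    return d


def aggregate_score(results: Sequence[LocusResult]) -> float:
    """Arithmetic mean of per-locus distances over passing loci only."""
    distances = [r.distance for r in results if r.passed and r.distance is not None]
    if not distances:
        raise NoEvaluableLociError("no evaluable loci: every locus was discarded")
    return sum(distances) / len(distances)


def classify(score: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """MSI-positive iff score strictly exceeds the threshold."""
    return "MSI-positive" if score > threshold else "MSI-negative"


def evaluate_locus(
    locus: MicrosatelliteLocus,
    normal_dist: RepeatDistribution,
    tumor_dist: RepeatDistribution,
    cfg: QualityConfig,
) -> LocusResult:
    """QC one locus's pair of raw distributions and compute its distance."""
    normal_q = remove_outliers(normal_dist, cfg.outlier_sd)
    tumor_q = remove_outliers(tumor_dist, cfg.outlier_sd)
    result = LocusResult(
        locus=locus,
        status="pass",
        normal_counts=normal_q.counts,
        tumor_counts=tumor_q.counts,
    )
    if not normal_q or not tumor_q:
        result.status = "discarded:no_support"
        return result
    if not locus_passes_coverage(normal_q, tumor_q, cfg.min_locus_coverage):
        result.status = "discarded:low_coverage"
        return result
    result.normal_norm = normalize(normal_q)
    result.tumor_norm = normalize(tumor_q)
    result.distance = stepwise_difference(result.tumor_norm, result.normal_norm)
    return result


def score_pair(
    normal_bam: str | Path,
    tumor_bam: str | Path,
    loci: Sequence[MicrosatelliteLocus],
    reference: str | Path | None = None,
    cfg: QualityConfig | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    output_prefix: str | Path | None = None,
) -> PairResult:
    """Run the full per-locus pipeline over a tumor-normal pair and aggregate.

    ``loci`` should already be realigned against the reference (``parse_bed``
    does this).  Locus order in the output follows the input; per-locus
    computations are independent of each other, so ordering never changes any
    value.  When ``output_prefix`` is given, per-locus and summary TSVs are
    written as ``<prefix>.loci.tsv`` and ``<prefix>.summary.tsv``.
    """
    cfg = cfg or QualityConfig()
    with pysam.AlignmentFile(str(normal_bam)) as nbam, \
         pysam.AlignmentFile(str(tumor_bam)) as tbam:
        results = []
        for locus in loci:
            normal_dist, ntally = locus_distribution(nbam, locus, cfg, "normal")
            tumor_dist, ttally = locus_distribution(tbam, locus, cfg, "tumor")
            if ntally or ttally:
                logger.debug(
                    "%s rejections normal=%s tumor=%s", locus.region, ntally, ttally
                )
            results.append(evaluate_locus(locus, normal_dist, tumor_dist, cfg))
    score = aggregate_score(results)
    pair = PairResult(
        locus_results=results,
        aggregate=score,
        threshold=threshold,
        call=classify(score, threshold),
    )
    if output_prefix is not None:
        write_pair_outputs(pair, output_prefix)
    return pair


def _fmt_counts(counts: dict[int, int]) -> str:
    return ",".join(f"{r}:{c}" for r, c in sorted(counts.items())) or "."


def write_pair_outputs(pair: PairResult, prefix: str | Path) -> tuple[Path, Path]:
    """Write the per-locus table and the run summary as TSV files."""
    prefix = Path(prefix)
    loci_path = prefix.with_name(prefix.name + ".loci.tsv")
    summary_path = prefix.with_name(prefix.name + ".summary.tsv")
    with open(loci_path, "w") as fh:
        fh.write("locus\tmotif\tstatus\tnormal_counts\ttumor_counts\tdifference\n")
        for r in pair.locus_results:
            diff = f"{r.distance:.6f}" if r.distance is not None else "."
            fh.write(
                f"{r.locus.region}\t{r.locus.name}\t{r.status}\t"
                f"{_fmt_counts(r.normal_counts)}\t{_fmt_counts(r.tumor_counts)}\t{diff}\n"
            )
    with open(summary_path, "w") as fh:
        fh.write(f"Average_Difference\t{pair.aggregate:.6f}\n")
        fh.write(f"Threshold\t{pair.threshold:.6f}\n")
        fh.write(f"Call\t{pair.call}\n")
        fh.write(f"Loci_Pass\t{pair.n_pass}\n")
        fh.write(f"Loci_Discarded\t{pair.n_discarded}\n")
    return loci_path, summary_path
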