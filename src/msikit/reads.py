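"""Read extraction, quality control and per-read repeat counting.

For each microsatellite locus, reads that fully span the run (plus a small
flank) are pulled from the alignment, filtered in a fixed order, and the
number of consecutive motif copies in each surviving read is counted by
exact string matching.  Indels within the run are precisely the signal being
measured, so the run is read from the base sequence, never "repaired"
through the CIGAR.  The per-sample histogram of repeat counts over accepted
reads is the repeat-length distribution handed to scoring.

Filter order (a read carries the first failure only):
spanning -> length -> read quality -> motif location -> truncation -> locus quality
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pysam

from .loci import MicrosatelliteLocus

logger = logging.getLogger(__name__)

Rejection = Literal[
    "not_spanning",
    "too_short",
    "low_read_quality",
    "motif_not_found",
    "truncated_run",
    "low_locus_quality",
]

#: anchor bases required on each side of the run for the spanning test
FLANK = 1
#: search half-window (bases) around the projected motif start
START_SEARCH_WINDOW = 2


@dataclass(frozen=True)
class QualityConfig:
    """Read- and locus-level QC thresholds.

    Defaults follow whole-exome guidance: reads shorter than 35 bp or with
    mean Phred below 20 are dropped; the run itself must average Phred 25;
    a locus needs 20 accepted reads in each sample; repeat lengths beyond
    3 standard deviations of the (support-weighted) mean are outliers.
    """

    min_read_length: int = 35
    min_read_quality: float = 20.0
    min_locus_quality: float = 25.0
    min_locus_coverage: int = 20
    outlier_sd: float = 3.0

    def __post_init__(self) -> None:
        if min(self.min_read_length, self.min_read_quality,
               self.min_locus_quality, self.min_locus_coverage) < 0:
            raise ValueError("QC thresholds must be non-negative")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")


@dataclass
class ReadObservation:
    """One read overlapping a locus, with its QC fate and repeat count."""

    read_id: str
    sequence: str
    base_qualities: Sequence[int]
    aln_start: int
    aln_end: int
    #: query-coordinate projection of locus.start through the alignment
    motif_hint: int | None = None
    repeat_count: int | None = None
    rejection: Rejection | None = None


@dataclass
class RepeatDistribution:
    """Histogram of motif repeat counts supported by accepted reads."""

    counts: dict[int, int] = field(default_factory=dict)
    sample_role: Literal["normal", "tumor"] = "normal"

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __bool__(self) -> bool:
        return self.total > 0


def fetch_spanning_reads(
    alignment: "pysam.AlignmentFile | str | Path",
    locus: MicrosatelliteLocus,
    flank: int = FLANK,
) -> list[ReadObservation]:
    """Extract reads whose aligned span contains the locus plus ``flank``.

    Unmapped, secondary, supplementary and duplicate-flagged reads are never
    considered.  Reads overlapping but not fully spanning
    ``[start - flank, end + flank)`` are returned with rejection
    ``not_spanning`` so that QC tallies are complete.
    """
    bam = _open_bam(alignment)
    if locus.chrom not in bam.references:
        logger.warning("contig %s absent from alignment header; locus skipped", locus.chrom)
        return []
    lo, hi = locus.start - flank, locus.end + flank
    out: list[ReadObservation] = []
    for read in bam.fetch(locus.chrom, max(lo, 0), hi):
        if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
            continue
        if read.query_sequence is None or read.query_qualities is None:
            continue
        obs = ReadObservation(
            read_id=read.query_name,
            sequence=read.query_sequence.upper(),
            base_qualities=list(read.query_qualities),
            aln_start=read.reference_start,
            aln_end=read.reference_end,
        )
        if read.reference_start > lo or read.reference_end < hi:
            obs.rejection = "not_spanning"
        else:
            obs.motif_hint = _project_position(read, locus.start)
        out.append(obs)
    return out


def _project_position(read: "pysam.AlignedSegment", ref_pos: int) -> int:
    """Query-coordinate of ``ref_pos``; nearest aligned base if it falls in a deletion."""
    best_q, best_dist = 0, None
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == ref_pos:
            return qpos
        dist = abs(rpos - ref_pos)
        if best_dist is None or dist < best_dist:
            # shift by the residual so the hint lands where ref_pos would sit
            best_q, best_dist = qpos + (ref_pos - rpos), dist
    return max(0, min(best_q, len(read.query_sequence) - 1))


def apply_read_filters(read: ReadObservation, cfg: QualityConfig) -> ReadObservation:
    """Stage-1 QC: minimum length, then minimum mean base quality (strict <)."""
    if read.rejection is not None:
        return read
    if len(read.sequence) < cfg.min_read_length:
        read.rejection = "too_short"
    elif float(np.mean(read.base_qualities)) < cfg.min_read_quality:
        read.rejection = "low_read_quality"
    return read


def count_repeats(
    read: ReadObservation,
    locus: MicrosatelliteLocus,
    cfg: QualityConfig,
    search_window: int = START_SEARCH_WINDOW,
) -> ReadObservation:
    """Count consecutive exact motif copies in the read; stage-2 QC.

    The run start is located by exact-match adjustment within
    ``+/- search_window`` bases of the alignment-projected locus start, then
    anchored to the left edge of the run.  The count is the whole number of
    consecutive copies (partial trailing copies are ignored).  A run whose
    periodic extension reaches either end of the read sequence may continue
    beyond the read, so the read is rejected as ``truncated_run``; a run with
    mean base quality below ``min_locus_quality`` is rejected as
    ``low_locus_quality``.
    """
    if read.rejection is not None:
        return read
    seq, motif, u = read.sequence, locus.motif, locus.unit
    hint = read.motif_hint if read.motif_hint is not None else 0

    start = None
    for off in sorted(range(-search_window, search_window + 1), key=abs):
        pos = hint + off
        if 0 <= pos <= len(seq) - u and seq[pos : pos + u] == motif:
            start = pos
            break
    if start is None:
        read.rejection = "motif_not_found"
        return read

    # anchor at the left edge of the run of whole copies
    while start >= u and seq[start - u : start] == motif:
        start -= u
    end = start + u
    while end + u <= len(seq) and seq[end : end + u] == motif:
        end += u
    copies = (end - start) // u

    if _touches_read_edge(seq, motif, start, end):
        read.rejection = "truncated_run"
        return read
    if float(np.mean(np.asarray(read.base_qualities)[start:end])) < cfg.min_locus_quality:
        read.rejection = "low_locus_quality"
        return read
    read.repeat_count = copies
    return read


def _touches_read_edge(seq: str, motif: str, start: int, end: int) -> bool:
    """Does the run (including partial-copy extension) abut a read boundary?"""
    u = len(motif)
    if start == 0 or end == len(seq):
        return True
    # partial copy continuing toward the 3' end
    k = 0
    while end + k < len(seq) and seq[end + k] == motif[k % u]:
        k += 1
    if end + k == len(seq):
        return True
    # partial copy continuing toward the 5' end
    j = 0
    while start - 1 - j >= 0 and seq[start - 1 - j] == motif[(u - 1 - j) % u]:
        j += 1
    return start - j == 0 and j > 0


def build_distribution(
    reads: Iterable[ReadObservation], role: Literal["normal", "tumor"]
) -> RepeatDistribution:
    """Histogram accepted reads' repeat counts; rejected reads contribute nothing."""
    counts = Counter(
        r.repeat_count for r in reads if r.rejection is None and r.repeat_count is not None
    )
    return RepeatDistribution(counts=dict(sorted(counts.items())), sample_role=role)


def rejection_tally(reads: Iterable[ReadObservation]) -> dict[str, int]:
    return dict(Counter(r.rejection for r in reads if r.rejection is not None))


def locus_distribution(
    alignment: "pysam.AlignmentFile | str | Path",
    locus: MicrosatelliteLocus,
    cfg: QualityConfig,
    role: Literal["normal", "tumor"],
) -> tuple[RepeatDistribution, dict[str, int]]:
    """Full per-locus read pipeline for one sample: fetch, filter, count."""
    reads = fetch_spanning_reads(alignment, locus)
    for r in reads:
        apply_read_filters(r, cfg)
        count_repeats(r, locus, cfg)
    return build_distribution(reads, role), rejection_tally(reads)


def _open_bam(alignment: "pysam.AlignmentFile | str | Path") -> pysam.AlignmentFile:
    if isinstance(alignment, pysam.AlignmentFile):
        return alignment
    return pysam.AlignmentFile(str(alignment))
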