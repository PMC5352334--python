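"""Microsatellite discovery: scan a reference genome for short tandem repeats.

Finds every maximal, left-most-anchored run of a primitive 1-6 bp motif that
meets a per-unit-length minimum copy number, and emits the annotated 6-column
BED consumed by the caller.  Runs whose motif is a repetition of a shorter
motif (e.g. ``ACAC``) are reported once, under the primitive form; ambiguous
bases terminate runs, so reported copy numbers are exact against the
reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pysam

from .loci import MicrosatelliteLocus, is_primitive

_ACGT_SEGMENT = re.compile(r"[ACGT]+")

#: conventional defaults: homopolymer panels start at 6 copies, longer units at 3.
DEFAULT_MIN_REPEATS = {1: 6, 2: 3, 3: 3, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class MotifSpec:
    """Scan request: motif unit length and the minimum copies to report."""

    unit_length: int
    min_repeats: int

    def __post_init__(self) -> None:
        if not (1 <= self.unit_length <= 6):
            raise ValueError(f"unit_length must be in [1, 6], got {self.unit_length}")
        if self.min_repeats < 2:
            raise ValueError(f"min_repeats must be >= 2, got {self.min_repeats}")


def default_specs(
    min_repeats_mono: int = 6, min_repeats_multi: int = 3, max_unit: int = 6
) -> list[MotifSpec]:
    return [
        MotifSpec(u, min_repeats_mono if u == 1 else min_repeats_multi)
        for u in range(1, max_unit + 1)
    ]


def scan_sequence(
    seq: str, specs: list[MotifSpec], chrom: str = "seq"
) -> list[MicrosatelliteLocus]:
    """Scan one sequence for maximal primitive-motif runs.

    For each requested unit length the sequence is swept once: a run is the
    maximal stretch with period ``u`` starting at a left-maximal position,
    and its copy number is the whole number of motif copies it contains
    (trailing partial copies are ignored).  Non-ACGT characters split the
    sequence into independently scanned segments.
    """
    if not specs:
        raise ValueError("at least one MotifSpec is required")
    seq = seq.upper()
    found: list[MicrosatelliteLocus] = []
    for segment in _ACGT_SEGMENT.finditer(seq):
        s, text = segment.start(), segment.group(0)
        for spec in specs:
            found.extend(_scan_segment(text, s, spec, chrom))
    found.sort(key=lambda l: (l.chrom, l.start, l.unit))
    return found


def _scan_segment(
    text: str, offset: int, spec: MotifSpec, chrom: str
) -> list[MicrosatelliteLocus]:
    u, n = spec.unit_length, len(text)
    out: list[MicrosatelliteLocus] = []
    i = 0
    while i + u * spec.min_repeats <= n:
        # maximal period-u extension from i
        j = i + u
        while j < n and text[j] == text[j - u]:
            j += 1
        copies = (j - i) // u
        if copies >= spec.min_repeats:
            motif = text[i : i + u]
            if is_primitive(motif):
                out.append(
                    MicrosatelliteLocus(
                        chrom=chrom,
                        start=offset + i,
                        end=offset + i + u * copies,
                        motif=motif,
                        ref_repeats=copies,
                    )
                )
        # every start in (i, j-u] lies inside this period run and is not
        # left-maximal; resume just past it
        i = max(i + 1, j - u + 1)
    return out


def scan_reference(
    reference: str | Path | pysam.FastaFile, specs: list[MotifSpec]
) -> list[MicrosatelliteLocus]:
    """Scan every contig of a FASTA reference; loci sorted by (chrom, start)."""
    if not specs:
        raise ValueError("at least one MotifSpec is required")
    ref = reference if isinstance(reference, pysam.FastaFile) else pysam.FastaFile(str(reference))
    loci: list[MicrosatelliteLocus] = []
    for chrom in ref.references:
        loci.extend(scan_sequence(ref.fetch(chrom), specs, chrom=chrom))
    loci.sort(key=lambda l: (l.chrom, l.start, l.unit))
    return loci
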