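"""Microsatellite locus records, the annotated BED dialect, and reference realignment.

A locus is a maximal run of a short (1-6 bp) motif in the reference genome.
Target loci travel in a 6-column BED file whose name field encodes the motif
and its reference copy number, e.g. ``(AC)12``.  Coordinates are 0-based
half-open throughout the package, matching BED.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

logger = logging.getLogger(__name__)

_NAME_RE = re.compile(r"^\(([ACGT]+)\)(\d+)$")

#: offsets tried when reconciling BED coordinates against the reference;
#: covers 0- vs 1-based bookkeeping, nothing larger.
REALIGN_OFFSETS = (0, -1, 1)


class LociError(Exception):
    """Raised for unrecoverable locus input problems (e.g. no parsable loci)."""


@dataclass(frozen=True, order=True)
class MicrosatelliteLocus:
    """A microsatellite run in the reference genome.

    ``end - start == len(motif) * ref_repeats`` and the reference sequence over
    ``[start, end)`` is exactly ``motif`` repeated ``ref_repeats`` times.
    """

    chrom: str
    start: int
    end: int
    motif: str
    ref_repeats: int

    def __post_init__(self) -> None:
        if not (1 <= len(self.motif) <= 6):
            raise ValueError(f"motif length must be 1-6, got {self.motif!r}")
        if self.motif != self.motif.upper() or set(self.motif) - set("ACGT"):
            raise ValueError(f"motif must be uppercase ACGT, got {self.motif!r}")
        if self.ref_repeats < 2:
            raise ValueError(f"ref_repeats must be >= 2, got {self.ref_repeats}")
        if self.end - self.start != len(self.motif) * self.ref_repeats:
            raise ValueError(
                f"span {self.end - self.start} != {len(self.motif)} x {self.ref_repeats}"
            )

    @property
    def unit(self) -> int:
        return len(self.motif)

    @property
    def name(self) -> str:
        """The BED name field, e.g. ``(AC)12``."""
        return f"({self.motif}){self.ref_repeats}"

    @property
    def region(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def is_primitive(motif: str) -> bool:
    """True if ``motif`` is not itself a repetition of a shorter motif."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def write_loci_bed(loci: Iterable[MicrosatelliteLocus], path: str | Path) -> None:
    """Write loci as 6-column BED: chrom, start, end, (MOTIF)N, 0, +."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.name}\t0\t+\n")


def parse_name_field(name: str) -> tuple[str, int]:
    """Decompose a ``(AC)12``-style name field into (motif, repeat count)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"name field {name!r} does not match (MOTIF)N")
    return m.group(1), int(m.group(2))


def parse_bed(
    path: str | Path,
    reference: "pysam.FastaFile | str | Path | None" = None,
    realign: bool = True,
) -> tuple[list[MicrosatelliteLocus], int]:
    """Parse the annotated 6-column BED into loci.

    Malformed lines are skipped with a logged warning; the number of skipped
    lines is returned alongside the loci.  When ``reference`` is given and
    ``realign`` is true, each locus is reconciled against the reference
    (see :func:`realign_locus`); loci that cannot be placed are dropped and
    counted as skipped.

    Raises :class:`LociError` if no line yields a usable locus.
    """
    ref = _open_fasta(reference) if reference is not None else None
    loci: list[MicrosatelliteLocus] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 4:
                    raise ValueError("fewer than 4 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                motif, reps = parse_name_field(fields[3])
                locus = MicrosatelliteLocus(chrom, start, end, motif, reps)
            except ValueError as exc:
                logger.warning("%s line %d skipped: %s", path, lineno, exc)
                skipped += 1
                continue
            if ref is not None and realign:
                fixed = realign_locus(locus, ref)
                if fixed is None:
                    logger.warning(
                        "%s line %d: locus %s %s not found in reference (+/-1); excluded",
                        path, lineno, locus.region, locus.name,
                    )
                    skipped += 1
                    continue
                locus = fixed
            loci.append(locus)
    if not loci:
        raise LociError(f"no parsable loci in {path}")
    return loci, skipped


def realign_locus(
    locus: MicrosatelliteLocus, reference: "pysam.FastaFile | str | Path"
) -> MicrosatelliteLocus | None:
    """Reconcile a locus against the reference and maximize its repeat run.

    BED files produced with 1-based coordinates place the run one base off;
    offsets of 0, -1 and +1 from the stated start are tried, in that order.
    Once anchored, the run is extended to the maximal stretch of the motif in
    the reference and ``ref_repeats`` updated.  Returns ``None`` when the
    motif run is absent at every candidate offset (the locus is unusable).
    """
    ref = _open_fasta(reference)
    if locus.chrom not in ref.references:
        return None
    u = locus.unit
    expected = locus.motif * locus.ref_repeats
    span = len(expected)
    clen = ref.get_reference_length(locus.chrom)
    for off in REALIGN_OFFSETS:
        start = locus.start + off
        if start < 0 or start + span > clen:
            continue
        if ref.fetch(locus.chrom, start, start + span).upper() != expected:
            continue
        # anchor found: extend to the maximal run of whole motif copies
        end = start + span
        while start >= u and ref.fetch(locus.chrom, start - u, start).upper() == locus.motif:
            start -= u
        while end + u <= clen and ref.fetch(locus.chrom, end, end + u).upper() == locus.motif:
            end += u
        return replace(locus, start=start, end=end, ref_repeats=(end - start) // u)
    return None


def _open_fasta(reference: "pysam.FastaFile | str | Path") -> pysam.FastaFile:
    if isinstance(reference, pysam.FastaFile):
        return reference
    return pysam.FastaFile(str(reference))
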