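"""Seeded synthetic data: reference genomes with planted microsatellites and
paired normal/tumor alignment files with configurable repeat-length
distributions.

The generator states a small, fully known world so every downstream module
can be tested against exact truth: planted loci are flanked by bases that
cannot extend the run, background sequence is scrubbed of accidental
microsatellites, and reads are written pre-aligned with CIGARs encoding the
insertion or deletion implied by each read's drawn repeat count.  Base
errors, when enabled, are injected only outside the run by default, so drawn
distributions remain exactly recoverable.  All randomness flows from one
integer seed; identical seeds give identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .catalog import MotifSpec, default_specs, scan_sequence
from .loci import MicrosatelliteLocus, write_loci_bed

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

DEFAULT_DEPTH = 50
DEFAULT_READ_LENGTH = 100
DEFAULT_QUALITY = 30


@dataclass(frozen=True)
class SimulatedLocusSpec:
    """Per-locus simulation recipe for one tumor-normal pair.

    ``normal_dist``/``tumor_dist`` map repeat count -> probability and must
    each sum to 1.  A ``tumor_dist`` of None mirrors the normal sample's
    drawn counts read-for-read, making the pair exactly stable at the locus.
    """

    locus: MicrosatelliteLocus
    normal_dist: dict[int, float]
    tumor_dist: dict[int, float] | None = None
    depth_normal: int = DEFAULT_DEPTH
    depth_tumor: int = DEFAULT_DEPTH
    base_error_rate: float = 0.0
    quality_mean: int = DEFAULT_QUALITY

    def __post_init__(self) -> None:
        for name, dist in (("normal_dist", self.normal_dist), ("tumor_dist", self.tumor_dist)):
            if dist is None:
                continue
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
            if any(r < 1 for r in dist):
                raise ValueError(f"{name} repeat counts must be >= 1")
        if min(self.depth_normal, self.depth_tumor) < 1:
            raise ValueError("depths must be >= 1")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise ValueError("base_error_rate must be in [0, 1)")


def make_reference(
    seed: int,
    loci: list[MicrosatelliteLocus],
    out_dir: str | Path,
    chrom_lengths: dict[str, int] | None = None,
    scrub_specs: list[MotifSpec] | None = None,
) -> tuple[Path, Path]:
    """Write a FASTA with the given loci planted in scrubbed random background.

    Chromosome lengths default to 200 bp past the last planted locus on each
    contig.  Flanking bases are chosen so no planted run can extend, and the
    background is re-rolled locally until a scan with ``scrub_specs``
    (default: the scanner's defaults) finds exactly the planted loci.
    Returns (fasta_path, truth_bed_path); the FASTA is faidx-indexed.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scrub_specs = scrub_specs if scrub_specs is not None else default_specs()

    loci = sorted(loci)
    by_chrom: dict[str, list[MicrosatelliteLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    for chrom, group in by_chrom.items():
        for a, b in zip(group, group[1:]):
            if b.start < a.end + 2:  # need a breakable flank base between runs
                raise ValueError(f"planted loci overlap or abut on {chrom}: {a} / {b}")

    chrom_lengths = dict(chrom_lengths or {})
    for chrom, group in by_chrom.items():
        chrom_lengths.setdefault(chrom, group[-1].end + 200)
        if group[-1].end + 1 > chrom_lengths[chrom] or group[0].start < 1:
            raise ValueError(f"planted loci out of bounds on {chrom}")

    fasta_path = out_dir / "reference.fa"
    bed_path = out_dir / "truth_loci.bed"
    with open(fasta_path, "w") as fh:
        for chrom in sorted(chrom_lengths):
            seq = _build_chromosome(
                rng, chrom, chrom_lengths[chrom], by_chrom.get(chrom, []), scrub_specs
            )
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    pysam.faidx(str(fasta_path))
    write_loci_bed(loci, bed_path)
    return fasta_path, bed_path


def _build_chromosome(
    rng: np.random.Generator,
    chrom: str,
    length: int,
    planted: list[MicrosatelliteLocus],
    scrub_specs: list[MotifSpec],
) -> str:
    seq = rng.choice(_BASES, size=length).tolist()
    frozen = np.zeros(length, dtype=bool)
    for loc in planted:
        seq[loc.start : loc.end] = list(loc.motif * loc.ref_repeats)
        frozen[loc.start : loc.end] = True
        # flanks that cannot continue the run in either direction
        seq[loc.start - 1] = _pick_base(rng, exclude={loc.motif[-1]})
        frozen[loc.start - 1] = True
        if loc.end < length:
            seq[loc.end] = _pick_base(rng, exclude={loc.motif[0]})
            frozen[loc.end] = True

    truth = {(l.start, l.end, l.motif) for l in planted}
    for _ in range(100):
        extra = [
            l
            for l in scan_sequence("".join(seq), scrub_specs, chrom=chrom)
            if (l.start, l.end, l.motif) not in truth
        ]
        if not extra:
            break
        for l in extra:
            mutable = [i for i in range(l.start, l.end) if not frozen[i]]
            if not mutable:  # spurious run inside a frozen region: cannot happen
                raise RuntimeError(f"unscrubbable run {l} overlaps planted locus")
            i = mutable[len(mutable) // 2]
            seq[i] = _pick_base(rng, exclude={seq[i]})
    else:
        raise RuntimeError(f"background scrub did not converge on {chrom}")
    return "".join(seq)


def _pick_base(rng: np.random.Generator, exclude: set[str]) -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return choices[int(rng.integers(len(choices)))]


def simulate_pair(
    reference: str | Path,
    specs: list[SimulatedLocusSpec],
    out_dir: str | Path,
    seed: int,
    read_length: int = DEFAULT_READ_LENGTH,
) -> tuple[Path, Path, "pd.DataFrame"]:
    """Write coordinate-sorted, indexed normal and tumor BAMs plus a truth table.

    For each locus and sample, per-read repeat counts are drawn from the
    spec's distribution; each read carries reference flanks around a run of
    ``motif x drawn`` with a CIGAR recording the length change versus the
    reference run.  Returns (normal_bam, tumor_bam, truth); ``truth`` has one
    row per (locus, sample) with the drawn histogram.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = pysam.FastaFile(str(reference))
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in zip(ref.references, ref.lengths)
        ],
    }

    truth_rows = []
    sample_reads: dict[str, list] = {"normal": [], "tumor": []}
    for spec in specs:
        loc = spec.locus
        max_reps = max(
            max(spec.normal_dist), max(spec.tumor_dist) if spec.tumor_dist else 0
        )
        if read_length < loc.unit * max_reps + 2 * (2 + 1):
            raise ValueError(
                f"read_length {read_length} too short for locus {loc.name}"
            )
        normal_counts = _draw_counts(rng, spec.normal_dist, spec.depth_normal)
        if spec.tumor_dist is None:
            tumor_counts = _mirror_counts(normal_counts, spec.depth_tumor)
        else:
            tumor_counts = _draw_counts(rng, spec.tumor_dist, spec.depth_tumor)
        for role, counts in (("normal", normal_counts), ("tumor", tumor_counts)):
            for k, drawn in enumerate(counts):
                sample_reads[role].append(
                    _make_read(rng, ref, loc, int(drawn), read_length, spec, f"{role}_{loc.region}_{k}")
                )
            hist = dict(zip(*np.unique(counts, return_counts=True)))
            truth_rows.append(
                {
                    "locus": loc.region,
                    "motif": loc.name,
                    "sample": role,
                    "counts": ",".join(f"{int(r)}:{int(c)}" for r, c in sorted(hist.items())),
                }
            )

    paths = {}
    for role, reads in sample_reads.items():
        unsorted = out_dir / f"{role}.unsorted.bam"
        final = out_dir / f"{role}.bam"
        with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
            for rec in reads:
                bam.write(rec.to_aligned_segment(bam.header))
        pysam.sort("-o", str(final), str(unsorted))
        unsorted.unlink()
        pysam.index(str(final))
        paths[role] = final

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return paths["normal"], paths["tumor"], truth


@dataclass
class _SimRead:
    name: str
    chrom: str
    pos: int
    seq: str
    qual: list[int]
    cigar: list[tuple[int, int]]

    def to_aligned_segment(self, header) -> pysam.AlignedSegment:
        a = pysam.AlignedSegment(header)
        a.query_name = self.name
        a.query_sequence = self.seq
        a.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in self.qual)
        )
        a.reference_name = self.chrom
        a.reference_start = self.pos
        a.cigartuples = self.cigar
        a.mapping_quality = 60
        a.flag = 0
        return a


def _draw_counts(
    rng: np.random.Generator, dist: dict[int, float], depth: int
) -> np.ndarray:
    values = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[v] for v in values], dtype=float)
    return rng.choice(values, size=depth, p=probs / probs.sum())


def _mirror_counts(normal_counts: np.ndarray, depth: int) -> np.ndarray:
    """Repeat-count multiset copied from the normal sample (recycled to depth)."""
    reps = int(np.ceil(depth / len(normal_counts)))
    return np.tile(normal_counts, reps)[:depth]


def _make_read(
    rng: np.random.Generator,
    ref: pysam.FastaFile,
    locus: MicrosatelliteLocus,
    drawn: int,
    read_length: int,
    spec: SimulatedLocusSpec,
    name: str,
) -> _SimRead:
    u = locus.unit
    run_len = u * drawn
    ref_run_len = u * locus.ref_repeats
    min_flank = 3  # covers the spanning margin plus start-search slack
    max_left = read_length - run_len - min_flank
    if max_left < min_flank:
        raise ValueError(f"read too short for locus {locus.name}")
    lf = int(rng.integers(min_flank, max_left + 1))
    rf = read_length - run_len - lf

    chrom_len = ref.get_reference_length(locus.chrom)
    if locus.start - lf < 0 or locus.end + rf > chrom_len:
        raise ValueError(f"flanks exceed contig bounds at {locus.region}")
    left = ref.fetch(locus.chrom, locus.start - lf, locus.start).upper()
    right = ref.fetch(locus.chrom, locus.end, locus.end + rf).upper()
    seq = left + locus.motif * drawn + right

    if spec.base_error_rate > 0:
        seq = _inject_errors(
            rng, seq, spec.base_error_rate, protect=range(lf, lf + run_len)
        )

    if drawn == locus.ref_repeats:
        cigar = [(0, read_length)]
    elif drawn > locus.ref_repeats:
        ins = run_len - ref_run_len
        cigar = [(0, lf + ref_run_len), (1, ins), (0, rf)]
    else:
        dele = ref_run_len - run_len
        cigar = [(0, lf + run_len), (2, dele), (0, rf)]

    qual = [spec.quality_mean] * read_length
    return _SimRead(
        name=name,
        chrom=locus.chrom,
        pos=locus.start - lf,
        seq=seq,
        qual=qual,
        cigar=cigar,
    )


#: primitive motifs cycled through when planting a standard test panel
_PANEL_MOTIFS = ("A", "AC", "AAT", "T", "AG", "C")
_PANEL_REPEATS = {1: 12, 2: 8, 3: 5}


def stable_pair_specs(
    seed: int,
    out_dir: str | Path,
    n_loci: int = 10,
    depth: int = DEFAULT_DEPTH,
    shift: int = 0,
    base_error_rate: float = 0.0,
    quality_mean: int = DEFAULT_QUALITY,
) -> tuple[Path, Path, list[SimulatedLocusSpec]]:
    """Build a standard synthetic world: reference plus per-locus recipes.

    Plants ``n_loci`` microsatellites (motifs cycled over homopolymers,
    dimers and trimers) 200 bp apart on one contig.  Normal reads sit
    entirely at the reference repeat count; with ``shift`` > 0 tumor reads
    sit entirely at ``ref_repeats - shift`` (disjoint distributions), and
    with ``shift`` = 0 the tumor mirrors the normal read-for-read (an
    exactly stable pair).  Returns (fasta_path, truth_bed, specs) ready for
    :func:`simulate_pair`.
    """
    loci = []
    pos = 100
    for i in range(n_loci):
        motif = _PANEL_MOTIFS[i % len(_PANEL_MOTIFS)]
        reps = _PANEL_REPEATS[len(motif)]
        loci.append(
            MicrosatelliteLocus(
                chrom="chr1",
                start=pos,
                end=pos + len(motif) * reps,
                motif=motif,
                ref_repeats=reps,
            )
        )
        pos += len(motif) * reps + 200
    fasta, bed = make_reference(seed, loci, out_dir)
    specs = []
    for loc in loci:
        if shift > 0 and loc.ref_repeats - shift < 1:
            raise ValueError(f"shift {shift} leaves no repeats at {loc.name}")
        tumor = {loc.ref_repeats - shift: 1.0} if shift > 0 else None
        specs.append(
            SimulatedLocusSpec(
                locus=loc,
                normal_dist={loc.ref_repeats: 1.0},
                tumor_dist=tumor,
                depth_normal=depth,
                depth_tumor=depth,
                base_error_rate=base_error_rate,
                quality_mean=quality_mean,
            )
        )
    return fasta, bed, specs


def _inject_errors(
    rng: np.random.Generator, seq: str, rate: float, protect: range
) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in protect:
            continue
        if rng.random() < rate:
            out[i] = _pick_base(rng, exclude={out[i]})
    return "".join(out)
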