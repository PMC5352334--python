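"""Rank microsatellite loci by how well they separate MSI-H from MSS pairs.

Across a labeled cohort, each locus gets a difference of averages

    a = mean(d_i over covering MSI-H pairs) - mean(d_i over covering MSS pairs)

where d_i is the locus's distance in pair i and "covering" means the locus
passed coverage QC in that pair.  Because a locus observed in few pairs is
weakly supported, a is downweighted by the squared coverage proportion:

    l = a * c**2,   c = (pairs covering the locus) / (total pairs)

Loci are ranked by l descending (ties: higher c, then genomic order); the
top-n make a reduced BED panel.  Loci never covered in one of the label
groups have undefined a and rank last.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .loci import MicrosatelliteLocus, parse_name_field, write_loci_bed

logger = logging.getLogger(__name__)

_REGION_RE = re.compile(r"^(.+):(\d+)-(\d+)$")

LABEL_POSITIVE = "MSI-H"
LABEL_NEGATIVE = "MSS"


def load_cohort(
    results_dir: str | Path, labels: "pd.Series | str | Path"
) -> tuple[pd.DataFrame, pd.Series, dict[str, MicrosatelliteLocus]]:
    """Assemble the cohort distance table from per-pair ``*.loci.tsv`` outputs.

    Returns (table, labels, loci): ``table`` has one row per pair and one
    column per locus region, holding the locus distance where the locus
    passed QC in that pair and NaN otherwise; ``loci`` maps region strings
    back to locus records for BED output.
    """
    results_dir = Path(results_dir)
    if not isinstance(labels, pd.Series):
        lab = pd.read_csv(labels, sep="\t", header=None, names=["pair_id", "label"])
        labels = lab.set_index("pair_id")["label"]
    _check_labels(labels)

    rows: dict[str, dict[str, float]] = {}
    loci: dict[str, MicrosatelliteLocus] = {}
    files = sorted(results_dir.glob("*.loci.tsv"))
    if not files:
        raise FileNotFoundError(f"no *.loci.tsv files under {results_dir}")
    for path in files:
        pair_id = path.name[: -len(".loci.tsv")]
        if pair_id not in labels.index:
            raise KeyError(f"pair {pair_id!r} has no label")
        df = pd.read_csv(path, sep="\t")
        row: dict[str, float] = {}
        for rec in df.itertuples(index=False):
            region = rec.locus
            if region not in loci:
                loci[region] = _locus_from_fields(region, rec.motif)
            if rec.status == "pass":
                row[region] = float(rec.difference)
        rows[pair_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    table = table.reindex(index=labels.index)
    return table, labels, loci


def difference_of_averages(
    table: pd.DataFrame, labels: pd.Series, locus: str
) -> float:
    """Mean distance over covering MSI-H pairs minus mean over covering MSS pairs.

    NaN when the locus is covered by no MSI-H pair or no MSS pair (undefined).
    """
    _check_labels(labels)
    col = table[locus]
    h = col[labels == LABEL_POSITIVE].dropna()
    s = col[labels == LABEL_NEGATIVE].dropna()
    if h.empty or s.empty:
        return float("nan")
    return float(h.mean() - s.mean())


def locus_score(a: float, c: float) -> float:
    """Coverage-weighted discrimination score l = a * c**2."""
    if not (0.0 <= c <= 1.0):
        raise ValueError(f"coverage proportion must be in [0, 1], got {c}")
    return a * c * c


def rank_loci(table: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Score every locus and sort by (l desc, c desc, genomic order).

    Returns a DataFrame indexed by locus region with columns ``a``, ``c``,
    ``l``; loci with undefined a sort last (NaN l).
    """
    _check_labels(labels)
    labels = labels.reindex(table.index)
    n_pairs = len(table.index)
    records = []
    for region in table.columns:
        a = difference_of_averages(table, labels, region)
        c = float(table[region].notna().sum()) / n_pairs
        l = locus_score(a, c) if np.isfinite(a) else float("nan")
        chrom, start, _ = _split_region(region)
        records.append((region, a, c, l, chrom, start))
    df = pd.DataFrame(
        records, columns=["locus", "a", "c", "l", "_chrom", "_start"]
    ).set_index("locus")
    df = df.sort_values(
        by=["l", "c", "_chrom", "_start"],
        ascending=[False, False, True, True],
        na_position="last",
    )
    return df.drop(columns=["_chrom", "_start"])


def top_n_loci(
    ranking: pd.DataFrame,
    n: int,
    loci: dict[str, MicrosatelliteLocus],
    bed_path: str | Path | None = None,
) -> list[MicrosatelliteLocus]:
    """The n best-scoring loci, optionally written as a 6-column BED panel."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(ranking):
        logger.warning("requested top %d but only %d loci ranked", n, len(ranking))
        n = len(ranking)
    chosen = [loci[region] for region in ranking.index[:n]]
    if bed_path is not None:
        write_loci_bed(sorted(chosen), bed_path)
    return chosen


def _locus_from_fields(region: str, motif_field: str) -> MicrosatelliteLocus:
    chrom, start, end = _split_region(region)
    motif, reps = parse_name_field(motif_field)
    return MicrosatelliteLocus(chrom, start, end, motif, reps)


def _split_region(region: str) -> tuple[str, int, int]:
    m = _REGION_RE.match(region)
    if m is None:
        raise ValueError(f"malformed locus region {region!r}")
    return m.group(1), int(m.group(2)), int(m.group(3))


def _check_labels(labels: pd.Series) -> None:
    bad = set(labels.unique()) - {LABEL_POSITIVE, LABEL_NEGATIVE}
    if bad:
        raise ValueError(f"labels must be {LABEL_POSITIVE}/{LABEL_NEGATIVE}; got {bad}")
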