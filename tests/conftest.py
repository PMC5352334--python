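"""Shared fixtures: small simulated worlds reused across test modules."""

from __future__ import annotations

import pytest

from msikit.loci import parse_bed
from msikit.simulate import simulate_pair, stable_pair_specs


@pytest.fixture(scope="session")
def stable_world(tmp_path_factory):
    """A 10-locus reference with an exactly stable tumor-normal pair."""
    d = tmp_path_factory.mktemp("stable")
    fasta, bed, specs = stable_pair_specs(seed=101, out_dir=d, n_loci=10, shift=0)
    normal_bam, tumor_bam, truth = simulate_pair(fasta, specs, d, seed=102)
    loci, _ = parse_bed(bed, reference=fasta)
    return {
        "fasta": fasta, "bed": bed, "specs": specs, "loci": loci,
        "normal_bam": normal_bam, "tumor_bam": tumor_bam, "truth": truth,
    }


@pytest.fixture(scope="session")
def shifted_world(tmp_path_factory):
    """A 10-locus pair whose tumor runs are all 3 copies shorter than normal."""
    d = tmp_path_factory.mktemp("shifted")
    fasta, bed, specs = stable_pair_specs(seed=201, out_dir=d, n_loci=10, shift=3)
    normal_bam, tumor_bam, truth = simulate_pair(fasta, specs, d, seed=202)
    loci, _ = parse_bed(bed, reference=fasta)
    return {
        "fasta": fasta, "bed": bed, "specs": specs, "loci": loci,
        "normal_bam": normal_bam, "tumor_bam": tumor_bam, "truth": truth,
    }
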