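"""Stepwise distance, aggregation, classification, and the end-to-end pipeline."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msikit.loci import MicrosatelliteLocus
from msikit.reads import QualityConfig, RepeatDistribution
from msikit.scoring import (
    LocusResult,
    NoEvaluableLociError,
    NormalizedDistribution,
    aggregate_score,
    classify,
    evaluate_locus,
    normalize,
    score_pair,
    stepwise_difference,
)

LOCUS = MicrosatelliteLocus("chr1", 100, 120, "AC", 10)


def rd(counts, role="normal"):
    return RepeatDistribution(counts=counts, sample_role=role)


def nd(fracs):
    return NormalizedDistribution(fracs)


counts_strategy = st.dictionaries(
    keys=st.integers(min_value=2, max_value=40),
    values=st.integers(min_value=1, max_value=500),
    min_size=1,
    max_size=8,
)


class TestNormalize:
    def test_fractions(self):
        assert normalize(rd({10: 5, 12: 15})).fractions == {10: 0.25, 12: 0.75}

    def test_single_length(self):
        assert normalize(rd({12: 30})).fractions == {12: 1.0}

    def test_scale_invariance(self):
        a = normalize(rd({10: 5, 12: 15}))
        b = normalize(rd({10: 50, 12: 150}))
        assert a.fractions == b.fractions

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize(rd({}))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(counts=counts_strategy)
    def test_sums_to_one(self, counts):
        assert sum(normalize(rd(counts)).fractions.values()) == pytest.approx(1.0, abs=1e-9)


class TestStepwiseDifference:
    def test_identical_is_zero(self):
        a = nd({10: 0.5, 12: 0.5})
        assert stepwise_difference(a, a) == 0.0

    def test_disjoint_is_two(self):
        assert stepwise_difference(nd({12: 1.0}), nd({15: 1.0})) == 2.0

    def test_half_shift_is_one(self):
        assert stepwise_difference(nd({15: 0.5, 12: 0.5}), nd({15: 1.0})) == pytest.approx(1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=counts_strategy, b=counts_strategy)
    def test_matches_dense_l1_oracle(self, a, b):
        """d equals the L1 norm of dense fraction vectors over the length range."""
        ta, tb = normalize(rd(a)), normalize(rd(b))
        lo = min(min(a), min(b))
        hi = max(max(a), max(b))
        va = np.array([ta.fractions.get(r, 0.0) for r in range(lo, hi + 1)])
        vb = np.array([tb.fractions.get(r, 0.0) for r in range(lo, hi + 1)])
        assert stepwise_difference(ta, tb) == pytest.approx(
            float(np.abs(va - vb).sum()), abs=1e-12
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=counts_strategy, b=counts_strategy)
    def test_symmetry_and_bounds(self, a, b):
        ta, tb = normalize(rd(a)), normalize(rd(b))
        d = stepwise_difference(ta, tb)
        assert d == stepwise_difference(tb, ta)
        assert 0.0 <= d <= 2.0 + 1e-12  # upper bound up to rounding
        # d = 2 iff the supports are disjoint (every count is >= 1 here)
        if set(a) & set(b):
            assert d < 2.0
        else:
            assert d == pytest.approx(2.0)

    def test_moving_mass_to_novel_length_never_decreases_d(self):
        normal = nd({15: 1.0})
        prev = -1.0
        for shifted in np.linspace(0.0, 1.0, 11):
            tumor = nd({15: 1.0 - shifted, 11: shifted})
            d = stepwise_difference(tumor, normal)
            assert d >= prev
            prev = d


class TestAggregateAndClassify:
    def test_mean_of_distances(self):
        results = [
            LocusResult(LOCUS, "pass", distance=d) for d in (0.0, 1.0, 2.0)
        ]
        assert aggregate_score(results) == pytest.approx(1.0)

    def test_discarded_loci_excluded(self):
        results = [
            LocusResult(LOCUS, "pass", distance=0.37),
            LocusResult(LOCUS, "discarded:low_coverage"),
        ]
        assert aggregate_score(results) == pytest.approx(0.37)

    def test_no_passing_loci_fatal(self):
        with pytest.raises(NoEvaluableLociError):
            aggregate_score([LocusResult(LOCUS, "discarded:no_support")])

    @pytest.mark.parametrize(
        "score,threshold,expected",
        [
            (0.5, 0.4, "MSI-positive"),
            (0.4, 0.4, "MSI-negative"),  # strict inequality at the threshold
            (0.0, 0.4, "MSI-negative"),
            (0.41, 0.4, "MSI-positive"),
        ],
    )
    def test_classify(self, score, threshold, expected):
        assert classify(score, threshold) == expected


class TestEvaluateLocus:
    def test_passing_locus(self):
        res = evaluate_locus(LOCUS, rd({10: 30}), rd({7: 30}, "tumor"), QualityConfig())
        assert res.passed and res.distance == pytest.approx(2.0)

    def test_low_coverage_discarded(self):
        res = evaluate_locus(LOCUS, rd({10: 30}), rd({10: 5}, "tumor"), QualityConfig())
        assert res.status == "discarded:low_coverage"

    def test_empty_after_qc_discarded(self):
        res = evaluate_locus(LOCUS, rd({}), rd({10: 30}, "tumor"), QualityConfig())
        assert res.status == "discarded:no_support"

    def test_depth_invariance(self):
        """Scaling either sample's counts by k never changes the distance."""
        base = evaluate_locus(
            LOCUS, rd({10: 20, 12: 40}), rd({10: 30, 9: 60}, "tumor"), QualityConfig()
        )
        for k in (2, 10, 100):
            scaled = evaluate_locus(
                LOCUS,
                rd({10: 20 * k, 12: 40 * k}),
                rd({10: 30, 9: 60}, "tumor"),
                QualityConfig(),
            )
            assert scaled.distance == pytest.approx(base.distance, abs=1e-12)


class TestScorePairEndToEnd:
    def test_identity_pair_scores_zero(self, stable_world):
        pair = score_pair(
            stable_world["normal_bam"], stable_world["tumor_bam"], stable_world["loci"]
        )
        assert pair.aggregate == 0.0
        assert pair.call == "MSI-negative"
        assert pair.n_pass == len(stable_world["loci"])

    def test_disjoint_pair_scores_two(self, shifted_world):
        pair = score_pair(
            shifted_world["normal_bam"], shifted_world["tumor_bam"], shifted_world["loci"]
        )
        assert pair.aggregate == 2.0
        assert pair.call == "MSI-positive"

    def test_locus_order_does_not_change_values(self, shifted_world):
        fwd = score_pair(
            shifted_world["normal_bam"], shifted_world["tumor_bam"], shifted_world["loci"]
        )
        rev = score_pair(
            shifted_world["normal_bam"],
            shifted_world["tumor_bam"],
            list(reversed(shifted_world["loci"])),
        )
        assert fwd.aggregate == rev.aggregate
        assert {r.locus: r.distance for r in fwd.locus_results} == {
            r.locus: r.distance for r in rev.locus_results
        }

    def test_output_files(self, shifted_world, tmp_path):
        prefix = tmp_path / "pair1"
        score_pair(
            shifted_world["normal_bam"],
            shifted_world["tumor_bam"],
            shifted_world["loci"],
            output_prefix=prefix,
        )
        loci_tsv = tmp_path / "pair1.loci.tsv"
        summary = (tmp_path / "pair1.summary.tsv").read_text()
        lines = loci_tsv.read_text().splitlines()
        assert lines[0].split("\t") == [
            "locus", "motif", "status", "normal_counts", "tumor_counts", "difference",
        ]
        assert len(lines) == 1 + len(shifted_world["loci"])
        assert "Average_Difference\t2.000000" in summary
        assert "Call\tMSI-positive" in summary
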