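"""Consensus merging, size filtering, frequency annotation and strata."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvcohort import (
    ConsensusPolicy,
    annotate_frequency,
    consensus_merge,
    reciprocal_overlap,
    size_filter,
    stratify_frequency,
)
from cnvcohort.calls import InputFormatError

from conftest import make_calls


class TestReciprocalOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 100), (0, 100), 1.0),
            ((0, 100), (50, 150), 0.5),
            ((0, 100), (200, 300), 0.0),
            ((0, 100_000), (40_000, 140_000), 0.6),
        ],
    )
    def test_known_pairs(self, a, b, expected):
        assert reciprocal_overlap(*a, *b) == pytest.approx(expected)

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.integers(0, 10_000), min_size=4, max_size=4))
    def test_symmetric_and_bounded(self, xs):
        a0, a1, b0, b1 = xs
        if a0 == a1 or b0 == b1:
            return
        a0, a1 = min(a0, a1), max(a0, a1)
        b0, b1 = min(b0, b1), max(b0, b1)
        ro = reciprocal_overlap(a0, a1, b0, b1)
        assert ro == reciprocal_overlap(b0, b1, a0, a1)
        assert 0.0 <= ro <= 1.0

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            reciprocal_overlap(10, 10, 0, 5)


class TestConsensusMerge:
    def test_identical_call_from_two_callers_merges(self):
        calls = make_calls(
            [("P1", "chr1", 0, 100_000, "DEL", "A"), ("P1", "chr1", 0, 100_000, "DEL", "B")]
        )
        out = consensus_merge(calls)
        assert len(out) == 1
        assert out.loc[0, "callers"] == "A,B"
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (0, 100_000)

    def test_single_caller_dropped_at_min_two(self):
        calls = make_calls([("P1", "chr1", 0, 100_000, "DEL", "A")])
        assert consensus_merge(calls).empty

    def test_partial_overlap_union_coordinates(self):
        # RO = 60k/100k = 0.6 >= 0.5 for both -> merged to the union extent
        calls = make_calls(
            [("P1", "chr1", 0, 100_000, "DEL", "A"), ("P1", "chr1", 40_000, 140_000, "DEL", "B")]
        )
        out = consensus_merge(calls)
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (0, 140_000)
        assert out.loc[0, "length"] == 140_000

    def test_different_types_never_merge(self):
        calls = make_calls(
            [("P1", "chr1", 0, 100_000, "DEL", "A"), ("P1", "chr1", 0, 100_000, "DUP", "B")]
        )
        assert consensus_merge(calls).empty

    def test_unknown_type_is_input_error(self):
        calls = make_calls([("P1", "chr1", 0, 100_000, "INV", "A")])
        with pytest.raises(InputFormatError):
            consensus_merge(calls)

    def test_order_independent(self, rng):
        rows = []
        for pid in ("P1", "P2"):
            for _ in range(8):
                s = int(rng.integers(0, 500_000))
                ln = int(rng.integers(20_000, 200_000))
                rows.append((pid, "chr1", s, s + ln, "DEL", rng.choice(["A", "B", "C"])))
        calls = make_calls(rows)
        base = consensus_merge(calls)
        for perm_seed in range(3):
            shuffled = calls.sample(frac=1.0, random_state=perm_seed).reset_index(drop=True)
            pd.testing.assert_frame_equal(consensus_merge(shuffled), base)


class TestSizeFilter:
    def test_boundary_inclusive(self):
        calls = make_calls(
            [("P1", "chr1", 0, 8_000, "DEL", "A,B"), ("P2", "chr1", 0, 10_000, "DEL", "A,B")],
            columns=("participant_id", "chrom", "start", "end", "type", "callers"),
        )
        out = size_filter(calls)
        assert list(out["participant_id"]) == ["P2"]

    def test_empty_input(self):
        out = size_filter(pd.DataFrame(columns=["participant_id", "chrom", "start", "end", "type"]))
        assert out.empty


def _brute_force_clusters(intervals, ro):
    """All-pairs connected components; independent oracle for clustering."""
    n = len(intervals)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        if reciprocal_overlap(*intervals[i], *intervals[j]) >= ro:
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestFrequencyAnnotation:
    def _consensus(self, rows):
        return make_calls(
            rows, columns=("participant_id", "chrom", "start", "end", "type", "callers")
        )

    def test_unique_call_frequency(self):
        calls = self._consensus([("P1", "chr1", 0, 50_000, "DEL", "A,B")])
        out = annotate_frequency(calls, n_participants=200)
        assert out.loc[0, "frequency"] == pytest.approx(0.005)

    def test_shared_locus_frequency(self):
        rows = [(f"P{i}", "chr1", 0, 50_000, "DEL", "A,B") for i in range(120)]
        out = annotate_frequency(self._consensus(rows), n_participants=1000)
        assert np.allclose(out["frequency"], 0.12)

    def test_disjoint_singletons(self):
        rows = [("P1", "chr1", 0, 50_000, "DEL", "A,B"), ("P2", "chr1", 200_000, 250_000, "DEL", "A,B")]
        out = annotate_frequency(self._consensus(rows), n_participants=100)
        assert out["cluster_id"].nunique() == 2
        assert np.allclose(out["frequency"], 0.01)

    def test_zero_cohort_is_error(self):
        with pytest.raises(ValueError):
            annotate_frequency(self._consensus([]), n_participants=0)

    def test_frequency_conservation(self, rng):
        rows = []
        for i in range(60):
            s = int(rng.integers(0, 400_000))
            ln = int(rng.integers(20_000, 100_000))
            rows.append((f"P{int(rng.integers(0, 30))}", "chr1", s, s + ln, "DEL", "A,B"))
        out = annotate_frequency(self._consensus(rows), n_participants=30)
        assert (out["frequency"] <= 1.0).all() and (out["frequency"] > 0).all()
        # sum over clusters of carrier counts equals the (participant, cluster) incidences
        inc = out.drop_duplicates(["participant_id", "cluster_id"])
        per_cluster = inc.groupby("cluster_id").size()
        for cid, cnt in per_cluster.items():
            sub = out[out["cluster_id"] == cid]
            assert sub["frequency"].iloc[0] == pytest.approx(cnt / 30)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_clustering_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 20))
        rows = []
        for i in range(m):
            s = int(rng.integers(0, 300_000))
            ln = int(rng.integers(10_000, 150_000))
            rows.append((f"P{i}", "chr1", s, s + ln, "DEL", "A,B"))
        out = annotate_frequency(self._consensus(rows), n_participants=m)
        ours = {
            frozenset(out.index[out["cluster_id"] == cid]) for cid in out["cluster_id"].unique()
        }
        oracle = _brute_force_clusters([(r[2], r[3]) for r in rows], 0.5)
        assert ours == oracle


class TestStratification:
    @pytest.mark.parametrize("f, expected", [(0.003, "rare"), (0.02, "less_rare"), (0.06, "common")])
    def test_strata_bounds(self, f, expected):
        calls = pd.DataFrame(
            {"participant_id": ["P1"], "chrom": ["chr1"], "start": [0], "end": [50_000],
             "type": ["DEL"], "frequency": [f]}
        )
        assert stratify_frequency(calls).loc[0, "stratum"] == expected

    def test_gap_folds_into_rare_with_warning(self, caplog):
        calls = pd.DataFrame(
            {"participant_id": ["P1"], "chrom": ["chr1"], "start": [0], "end": [50_000],
             "type": ["DEL"], "frequency": [0.007]}
        )
        with caplog.at_level(logging.WARNING):
            out = stratify_frequency(calls)
        assert out.loc[0, "stratum"] == "rare"
        assert any("rare" in rec.message for rec in caplog.records)

    def test_missing_frequency_is_error(self):
        calls = pd.DataFrame(
            {"participant_id": ["P1"], "chrom": ["chr1"], "start": [0], "end": [50_000],
             "type": ["DEL"]}
        )
        with pytest.raises(ValueError):
            stratify_frequency(calls)
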