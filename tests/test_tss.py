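"""TSS calling: clustering oracle, subcluster SDs, dependence criteria."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ivtseq.config import PipelineConfig
from ivtseq.models import FivePrimeTrack, ValidationError
from ivtseq.tss import (
    TSSCluster,
    call_tss,
    call_tss_table,
    cluster_positions,
    determine_dependence,
    filter_min_count,
    subcluster,
)


def oracle_single_linkage(positions, window):
    """Exhaustive single-linkage clustering via union-find over all pairs."""
    positions = sorted(positions)
    parent = {p: p for p in positions}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for a in positions:
        for b in positions:
            if a < b and b - a <= window:
                parent[find(a)] = find(b)
    groups = {}
    for p in positions:
        groups.setdefault(find(p), []).append(p)
    return sorted(sorted(g) for g in groups.values())


def population_sd(values):
    mean = sum(values) / len(values)
    return math.sqrt(sum((v - mean) ** 2 for v in values) / len(values))


positions_strategy = st.lists(
    st.integers(1, 5000), min_size=1, max_size=50, unique=True
)


class TestClusterPositions:
    @pytest.mark.parametrize(
        "positions,window,expected",
        [
            ([100, 150, 400], 100, [[100, 150], [400]]),
            ([42], 100, [[42]]),
            # chained gaps of exactly the window join (inclusive)
            ([1, 101, 201], 100, [[1, 101, 201]]),
            ([], 100, []),
        ],
    )
    def test_worked_examples(self, positions, window, expected):
        got = [c.members for c in cluster_positions(positions, window)]
        assert got == expected
        assert got == oracle_single_linkage(positions, window) if positions else True

    @given(positions_strategy, st.integers(1, 200))
    def test_matches_exhaustive_oracle(self, positions, window):
        got = [c.members for c in cluster_positions(positions, window)]
        assert got == oracle_single_linkage(positions, window)

    @given(positions_strategy, st.integers(1, 200))
    def test_partition_covers_input(self, positions, window):
        clusters = cluster_positions(positions, window)
        members = [p for c in clusters for p in c.members]
        assert sorted(members) == sorted(positions)


class TestSubcluster:
    @pytest.mark.parametrize(
        "members,expected",
        [
            ([100, 103, 105], [[100, 103, 105]]),  # SD ~ 2.05 < 10
            ([7], [[7]]),
            ([100, 150], [[100], [150]]),          # SD 25 >= 10 -> split
        ],
    )
    def test_worked_examples(self, members, expected):
        got = subcluster(TSSCluster("c", "+", members), 10)
        assert got == expected

    @given(positions_strategy, st.sampled_from(["+", "-"]))
    def test_runs_below_threshold_and_maximal(self, positions, strand):
        sd = 10.0
        runs = subcluster(TSSCluster("c", strand, positions), sd)
        assert sorted(p for r in runs for p in r) == sorted(positions)
        for r in runs:
            assert population_sd(r) < sd
        for a, b in zip(runs, runs[1:]):
            assert population_sd(a + b) >= sd  # maximal merging

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValidationError):
            subcluster(TSSCluster("c", "+", []), 10)


def make_tracks(counts_by_sample, contig="chr", strand="+"):
    return [
        FivePrimeTrack(s, {(contig, strand, p): c for p, c in by_pos.items()})
        for s, by_pos in counts_by_sample.items()
    ]


class TestCallTSS:
    def test_argmax_position_and_summed_count(self):
        tracks = make_tracks({"s1": {100: 10, 103: 2, 105: 1}})
        call = call_tss([100, 103, 105], "chr", "+", tracks)
        assert call.position == 100
        assert call.raw_sigma["s1"] == 13

    def test_singleton_identity(self):
        tracks = make_tracks({"s1": {200: 7}})
        call = call_tss([200], "chr", "+", tracks)
        assert (call.position, call.raw_sigma["s1"]) == (200, 7)

    @pytest.mark.parametrize("strand,winner", [("+", 100), ("-", 105)])
    def test_tie_breaks_most_upstream(self, strand, winner):
        tracks = make_tracks({"s1": {100: 5, 105: 5}}, strand=strand)
        call = call_tss([100, 105], "chr", strand, tracks)
        assert call.position == winner

    def test_control_counts_at_same_members(self):
        sigma = make_tracks({"s1": {100: 10, 101: 5}})
        control = make_tracks({"c1": {100: 2, 101: 1}})
        call = call_tss([100, 101], "chr", "+", sigma, control)
        assert call.raw_control["c1"] == 3


class TestFilterMinCount:
    def test_one_replicate_below_floor_fails(self):
        sigma = make_tracks({"s1": {10: 8}, "s2": {10: 3}})
        call = call_tss([10], "chr", "+", sigma)
        filter_min_count([call], {"s1": 1.0, "s2": 1.0}, 4.0)
        # normalized (8.0, 3.0): 3.0 < 4 in one replicate
        assert not call.passes_min_count

    @pytest.mark.parametrize(
        "counts,passes", [((4, 4), True), ((0, 0), False)]
    )
    def test_boundaries(self, counts, passes):
        sigma = make_tracks({"s1": {10: counts[0]}, "s2": {10: counts[1]}})
        call = call_tss([10], "chr", "+", sigma)
        filter_min_count([call], {"s1": 1.0, "s2": 1.0}, 4.0)
        assert call.passes_min_count is passes


class TestDependence:
    @pytest.mark.parametrize(
        "sigma,control,expected",
        [
            ((8, 10, 12), (1, 2), True),    # (i) 8>2, (ii) 10 >= 4*2
            ((5, 10, 12), (1, 2), True),
            ((5, 7, 12), (1, 2), False),    # (ii) 7 < 8
            ((4, 4), (0, 0), True),         # degenerate zero control
            ((8, 10), (9, 1), False),       # (i) fails: 8 <= 9
        ],
    )
    def test_truth_table(self, sigma, control, expected):
        assert determine_dependence(sigma, control, 4.0) is expected

    def test_single_sigma_replicate_rejected(self):
        with pytest.raises(ValidationError):
            determine_dependence([8.0], [1.0], 4.0)

    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=5),
        st.lists(st.floats(0, 100), min_size=1, max_size=4),
    )
    def test_ratio_monotonicity(self, sigma, control):
        # raising the ratio can only lose dependent calls
        if determine_dependence(sigma, control, 6.0):
            assert determine_dependence(sigma, control, 4.0)


class TestCallTable:
    @pytest.fixture
    def small_setup(self):
        sigma = make_tracks({"s1": {100: 20, 103: 4, 400: 9}, "s2": {100: 18, 400: 7}})
        control = make_tracks({"c1": {100: 1, 400: 8}, "c2": {400: 9}})
        factors = {"s1": 1.0, "s2": 1.0, "c1": 1.0, "c2": 1.0}
        return sigma, control, factors

    def test_count_conservation(self, small_setup):
        sigma, control, factors = small_setup
        calls = call_tss_table(sigma, control, factors, PipelineConfig())
        for t in sigma:
            total = sum(c.raw_sigma[t.sample_id] for c in calls)
            assert total == t.total()

    def test_dependence_respects_min_count(self, small_setup):
        sigma, control, factors = small_setup
        calls = call_tss_table(sigma, control, factors, PipelineConfig())
        for c in calls:
            if c.sigma_dependent:
                assert c.passes_min_count

    def test_dependent_call_found(self, small_setup):
        sigma, control, factors = small_setup
        calls = call_tss_table(sigma, control, factors, PipelineConfig())
        by_pos = {c.position: c for c in calls}
        assert by_pos[100].sigma_dependent        # strong sigma, weak control
        assert not by_pos[400].sigma_dependent    # similar in control

    @given(
        st.dictionaries(
            st.integers(1, 2000), st.integers(1, 50), min_size=1, max_size=30
        ),
        st.integers(1, 30),
    )
    def test_conservation_property(self, counts, extra):
        sigma = make_tracks({"s1": counts, "s2": dict(list(counts.items())[:extra])})
        calls = call_tss_table(sigma, [], {"s1": 1.0, "s2": 1.0}, PipelineConfig())
        for t in sigma:
            assert sum(c.raw_sigma[t.sample_id] for c in calls) == t.total()

    def test_strand_symmetry(self):
        """Mirroring coordinates and strand mirrors the called TSSs."""
        length = 3000
        fwd_counts = {("chr", "+", p): c for p, c in
                      [(100, 10), (103, 10), (120, 5), (900, 8)]}
        rev_counts = {("chr", "-", length + 1 - p): c
                      for (_, _, p), c in fwd_counts.items()}
        cfg = PipelineConfig()
        f1 = {"s1": 1.0, "s2": 1.0}
        fwd = call_tss_table(
            [FivePrimeTrack("s1", fwd_counts), FivePrimeTrack("s2", fwd_counts)],
            [], f1, cfg,
        )
        rev = call_tss_table(
            [FivePrimeTrack("s1", rev_counts), FivePrimeTrack("s2", rev_counts)],
            [], f1, cfg,
        )
        assert sorted(length + 1 - c.position for c in rev) == sorted(
            c.position for c in fwd
        )

    def test_min_count_monotonicity(self, small_setup):
        sigma, control, factors = small_setup
        dep = {}
        for floor in (4.0, 10.0):
            cfg = PipelineConfig(min_norm_count=floor)
            calls = call_tss_table(sigma, control, factors, cfg)
            dep[floor] = {c.position for c in calls if c.sigma_dependent}
        assert dep[10.0] <= dep[4.0]
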