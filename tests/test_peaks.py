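"""Gap filling, peak subgraphs, maximum-support paths, summits, trimming."""

import io

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphpeaks.model import (
    GraphGenome,
    GraphInterval,
    GraphPosition,
    build_linear_projection,
)
from graphpeaks.peaks import (
    Peak,
    connected_subgraphs,
    fill_gaps,
    find_max_path,
    peak_summit,
    peaks_to_linear,
    remove_short_peaks,
    trim_peak,
    with_summit,
    write_narrowpeak,
    write_peaks_jsonl,
)
from graphpeaks.tracks import PileupTrack, RegionSet, ScoreTrack

from _dag_oracles import fill_oracle, max_path_oracle
from _testutil import make_random_dag, random_alignment
from conftest import forward_read, make_chain_graph


def regions_from_linear(graph, included):
    rs = RegionSet.empty(graph)
    proj = build_linear_projection(graph)
    for node in graph.ref_path:
        base0 = proj.node_offsets[node]
        for o in range(graph.node_length(node)):
            if base0 + o in included:
                rs.masks[node][o] = True
    return rs


def random_regions(graph, rng, p=0.4):
    return RegionSet(
        {n: rng.random(graph.node_length(n)) < p for n in graph.nodes}
    )


class TestFillGaps:
    def test_short_chain_gap_joined(self):
        g = make_chain_graph(100, node_size=20)
        rs = regions_from_linear(g, set(range(0, 50)) | set(range(55, 100)))
        filled = fill_gaps(rs, 36, g)
        assert filled.n_bases == 100

    def test_gap_of_exactly_read_length_not_joined(self):
        g = make_chain_graph(200, node_size=50)
        rs = regions_from_linear(g, set(range(0, 50)) | set(range(86, 200)))
        filled = fill_gaps(rs, 36, g)
        assert filled.n_bases == rs.n_bases

    def test_only_short_parallel_branch_filled(self):
        g = GraphGenome(
            nodes={1: "A" * 20, 2: "C" * 10, 3: "G" * 40, 4: "T" * 20},
            edges={(1, 2), (1, 3), (2, 4), (3, 4)},
            ref_path=[1, 2, 4],
        )
        rs = RegionSet.empty(g)
        rs.masks[1][:] = True
        rs.masks[4][:] = True
        filled = fill_gaps(rs, 36, g)
        assert filled.masks[2].all()  # 10-base branch < 36: filled
        assert not filled.masks[3].any()  # 40-base branch: untouched

    def test_idempotent_and_monotone_on_chains(self):
        rng = np.random.default_rng(5)
        g = make_chain_graph(300, node_size=23)
        for _ in range(20):
            rs = random_regions(g, rng, p=0.3)
            once = fill_gaps(rs, 7, g)
            assert once.issuperset(rs)
            twice = fill_gaps(once, 7, g)
            assert all(
                np.array_equal(once.masks[n], twice.masks[n]) for n in g.nodes
            )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        mask=st.lists(st.booleans(), min_size=60, max_size=60),
        r=st.integers(min_value=1, max_value=12),
    )
    def test_chain_fill_is_monotone_and_idempotent(self, mask, r):
        g = make_chain_graph(60, node_size=20)
        rs = regions_from_linear(g, {i for i, b in enumerate(mask) if b})
        once = fill_gaps(rs, r, g)
        assert once.issuperset(rs)
        twice = fill_gaps(once, r, g)
        assert all(np.array_equal(once.masks[n], twice.masks[n]) for n in g.nodes)

    def test_matches_dfs_oracle_on_random_dags(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            g = make_random_dag(rng, max_nodes=10, max_node_len=4)
            rs = random_regions(g, rng, p=0.45)
            r = int(rng.integers(1, 7))
            got = fill_gaps(rs, r, g)
            want = fill_oracle(rs, r, g)
            for n in g.nodes:
                np.testing.assert_array_equal(
                    got.masks[n], want.masks[n], err_msg=f"node {n}, r={r}"
                )


class TestConnectedSubgraphs:
    def test_single_run_single_subgraph(self):
        g = make_chain_graph(100, node_size=50)
        rs = regions_from_linear(g, set(range(20, 80)))
        subs = connected_subgraphs(rs, g)
        assert len(subs) == 1
        assert subs[0].n_bases == 60

    def test_disjoint_bubble_arms_are_separate(self, bubble_graph):
        rs = RegionSet.empty(bubble_graph)
        rs.masks[2][:] = True
        rs.masks[3][:] = True
        subs = connected_subgraphs(rs, bubble_graph)
        assert len(subs) == 2
        assert [s.id for s in subs] == [0, 1]

    def test_components_match_networkx_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            g = make_random_dag(rng, max_nodes=10, max_node_len=4)
            rs = random_regions(g, rng, p=0.5)
            subs = connected_subgraphs(rs, g)
            bg = nx.Graph()
            for n, m in rs.masks.items():
                for o in range(len(m)):
                    if m[o]:
                        bg.add_node((n, o))
                    if o and m[o] and m[o - 1]:
                        bg.add_edge((n, o - 1), (n, o))
            for u, v in g.edges:
                if rs.masks[u][-1] and rs.masks[v][0]:
                    bg.add_edge((u, g.node_length(u) - 1), (v, 0))
            expect = {
                frozenset(c) for c in nx.connected_components(bg)
            }
            got = {
                frozenset((p.node, p.offset) for p in s.base_positions())
                for s in subs
            }
            assert got == expect


class TestFindMaxPath:
    def test_chain_subgraph_counts_contained_reads(self):
        g = make_chain_graph(200, node_size=50)
        rs = regions_from_linear(g, set(range(0, 150)))
        (sub,) = connected_subgraphs(rs, g)
        inside = [forward_read(g, [1], 0, 36, read_id="a")]
        crossing = [forward_read(g, [3, 4], 30, 16, read_id="b")]  # leaves the region
        peak = find_max_path(sub, inside + crossing, g)
        assert peak.support == 1
        assert peak.path.node_path == (1, 2, 3)
        assert peak.path.length(g) == 150

    def test_bubble_majority_allele_wins(self, bubble_graph):
        rs = RegionSet.empty(bubble_graph)
        for n in bubble_graph.nodes:
            rs.masks[n][:] = True
        (sub,) = connected_subgraphs(rs, bubble_graph)
        a = [forward_read(bubble_graph, [1, 2, 4], 3, 1, read_id=f"a{i}") for i in range(3)]
        b = [forward_read(bubble_graph, [1, 3, 4], 3, 1, read_id=f"b{i}") for i in range(7)]
        peak = find_max_path(sub, a + b, bubble_graph)
        assert peak.path.node_path == (1, 3, 4)
        assert peak.support == 7

    def test_tie_prefers_reference_branch(self, bubble_graph):
        rs = RegionSet.empty(bubble_graph)
        for n in bubble_graph.nodes:
            rs.masks[n][:] = True
        (sub,) = connected_subgraphs(rs, bubble_graph)
        a = [forward_read(bubble_graph, [1, 2, 4], 3, 1, read_id=f"a{i}") for i in range(3)]
        b = [forward_read(bubble_graph, [1, 3, 4], 3, 1, read_id=f"b{i}") for i in range(3)]
        peak = find_max_path(sub, a + b, bubble_graph)
        assert peak.path.node_path == (1, 2, 4)  # node 2 is the reference allele

    def test_matches_enumeration_oracle_on_random_dags(self):
        rng = np.random.default_rng(31)
        for _ in range(40):
            g = make_random_dag(rng, max_nodes=10, max_node_len=4)
            rs = random_regions(g, rng, p=0.6)
            alns = [random_alignment(g, rng, max_len=6) for _ in range(20)]
            for sub in connected_subgraphs(rs, g):
                peak = find_max_path(sub, alns, g)
                want_support, want_nodes = max_path_oracle(sub, alns, g)
                assert peak.support == want_support
                assert peak.path.node_path == want_nodes


class TestSummitTrimProject:
    def _qtrack(self, graph, scores_by_node):
        full = {
            n: np.asarray(
                scores_by_node.get(n, np.zeros(graph.node_length(n))), float
            )
            for n in graph.nodes
        }
        return ScoreTrack(scores=PileupTrack(full), kind="q")

    def test_remove_short_boundary_keeps_equal_length(self):
        g = make_chain_graph(600, node_size=1)

        def peak_of(length):
            return Peak(
                path=GraphInterval(tuple(range(1, length + 1)), 0, 1),
                support=0,
                subgraph_id=0,
            )

        peaks = [peak_of(199), peak_of(200), peak_of(201)]
        kept = remove_short_peaks(peaks, 200, g)
        assert [p.path.length(g) for p in kept] == [200, 201]
        assert remove_short_peaks(peaks, 1, g) == peaks

    def test_summit_is_leftmost_maximum(self):
        g = make_chain_graph(100, node_size=50)
        scores = np.zeros(100)
        scores[30:40] = 7.0  # plateau
        qt = self._qtrack(g, {1: scores[:50], 2: scores[50:]})
        peak = Peak(path=GraphInterval((1, 2), 0, 50), support=0, subgraph_id=0)
        pos, score = peak_summit(peak, qt, g)
        assert pos == GraphPosition(1, 30)
        assert score == 7.0

    def test_summit_matches_argmax_oracle(self):
        rng = np.random.default_rng(2)
        g = make_chain_graph(100, node_size=20)
        for _ in range(20):
            scores = rng.uniform(0, 5, 100)
            qt = self._qtrack(g, {i + 1: scores[20 * i : 20 * (i + 1)] for i in range(5)})
            peak = Peak(path=GraphInterval(tuple(range(1, 6)), 0, 20), support=0, subgraph_id=0)
            pos, score = peak_summit(peak, qt, g)
            k = int(np.argmax(scores))
            assert pos == GraphPosition(k // 20 + 1, k % 20)
            assert score == scores[k]

    def test_trim_centers_on_summit(self):
        g = make_chain_graph(500, node_size=100)
        peak = Peak(
            path=GraphInterval((1, 2, 3, 4, 5), 0, 100),
            support=0,
            subgraph_id=0,
            summit=GraphPosition(3, 50),  # linear 250
        )
        trimmed = trim_peak(peak, 120, g)
        assert trimmed.path.length(g) == 120
        bases = list(trimmed.path.bases(g))
        proj = build_linear_projection(g)
        lin = [proj.node_offsets[p.node] + p.offset for p in bases]
        assert lin[0] == 190 and lin[-1] == 309

    def test_trim_shifts_inward_near_path_start(self):
        g = make_chain_graph(500, node_size=100)
        peak = Peak(
            path=GraphInterval((1, 2, 3, 4, 5), 0, 100),
            support=0,
            subgraph_id=0,
            summit=GraphPosition(1, 10),
        )
        trimmed = trim_peak(peak, 120, g)
        bases = list(trimmed.path.bases(g))
        assert bases[0] == GraphPosition(1, 0)
        assert trimmed.path.length(g) == 120

    def test_trim_short_path_returned_whole(self, bubble_graph):
        peak = Peak(
            path=GraphInterval((1, 2, 4), 0, 2),
            support=0,
            subgraph_id=0,
            summit=GraphPosition(2, 0),
        )
        trimmed = trim_peak(peak, 120, bubble_graph)
        assert trimmed.path == peak.path

    def test_projection_collapses_alt_allele_to_reference_span(self, bubble_graph):
        proj = build_linear_projection(bubble_graph)
        ref_peak = Peak(
            path=GraphInterval((1, 2, 4), 0, 2), support=3, subgraph_id=0,
            summit=GraphPosition(1, 2), summit_qscore=4.0,
        )
        alt_peak = Peak(
            path=GraphInterval((1, 3, 4), 0, 2), support=3, subgraph_id=1,
            summit=GraphPosition(1, 2), summit_qscore=4.0,
        )
        lin = peaks_to_linear([ref_peak, alt_peak], proj, bubble_graph)
        assert (lin[0].start, lin[0].end) == (lin[1].start, lin[1].end) == (0, 7)

    def test_linear_output_sorted(self):
        g = make_chain_graph(300, node_size=100)
        proj = build_linear_projection(g)
        p1 = Peak(path=GraphInterval((3,), 0, 50), support=0, subgraph_id=1)
        p2 = Peak(path=GraphInterval((1,), 0, 50), support=0, subgraph_id=0)
        lin = peaks_to_linear([p1, p2], proj, g)
        assert [lp.start for lp in lin] == [0, 200]


class TestAlternativePeak:
    """Alternative path through the motif-matched part of a peak subgraph."""

    def _setup(self, graph):
        from graphpeaks.peaks import alternative_peak

        rs = RegionSet.empty(graph)
        for n in graph.nodes:
            rs.masks[n][:] = True
        (sub,) = connected_subgraphs(rs, graph)
        return alternative_peak, sub

    def _motif_pwm(self, consensus):
        from graphpeaks.evaluation import PWM

        counts = np.ones((len(consensus), 4))
        for i, b in enumerate(consensus):
            counts[i, "ACGT".index(b)] = 97.0
        return PWM.from_counts(counts)

    def _graph(self):
        # reference spells ACGTACGT|A|ACGTACGT; alt allele G at the bubble
        return GraphGenome(
            nodes={1: "ACGTACGT", 2: "A", 3: "G", 4: "ACGTACGT"},
            edges={(1, 2), (1, 3), (2, 4), (3, 4)},
            ref_path=[1, 2, 4],
        )

    def test_minority_allele_with_reads_is_reported(self):
        g = self._graph()
        alt_peak_fn, sub = self._setup(g)
        major = [forward_read(g, [1, 2, 4], 5, 3, read_id=f"a{i}") for i in range(5)]
        minor = [forward_read(g, [1, 3, 4], 5, 3, read_id=f"b{i}") for i in range(2)]
        # motif spans the SNP bubble on the main (reference-allele) path
        pwm = self._motif_pwm("ACGTAAC")
        alt = alt_peak_fn(sub, pwm, major + minor, g)
        assert alt is not None
        assert 3 in alt.path.node_path  # routed through the minority allele
        assert alt.support >= 2

    def test_no_motif_match_gives_nothing(self):
        g = self._graph()
        alt_peak_fn, sub = self._setup(g)
        reads = [forward_read(g, [1, 2, 4], 5, 3, read_id=f"a{i}") for i in range(3)]
        pwm = self._motif_pwm("GGGGGGGG")
        assert alt_peak_fn(sub, pwm, reads, g) is None

    def test_uncovered_alternative_gives_nothing(self):
        g = self._graph()
        alt_peak_fn, sub = self._setup(g)
        reads = [forward_read(g, [1, 2, 4], 5, 3, read_id=f"a{i}") for i in range(3)]
        pwm = self._motif_pwm("ACGTAAC")  # match on the main path
        assert alt_peak_fn(sub, pwm, reads, g) is None


def test_peak_writers_are_stable(bubble_graph):
    proj = build_linear_projection(bubble_graph)
    peak = Peak(
        path=GraphInterval((1, 3, 4), 0, 2), support=5, subgraph_id=0,
        summit=GraphPosition(3, 0), summit_qscore=3.21,
    )
    buf1, buf2 = io.StringIO(), io.StringIO()
    write_peaks_jsonl([peak], buf1)
    write_narrowpeak(peaks_to_linear([peak], proj, bubble_graph), buf2)
    assert '"node_path": [1, 3, 4]' in buf1.getvalue()
    cols = buf2.getvalue().split("\t")
    assert cols[0] == "graph" and cols[4] == "32"  # 10x q-score, rounded
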