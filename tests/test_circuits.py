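"""Regulatory graph construction, circuitry enumeration and scoring."""

import itertools

import numpy as np
import pytest

from crcpipe import (
    autoregulated_tfs,
    build_graph,
    enumerate_circuitries,
    report_crc,
    score_circuitries,
)
from .oracles import circuitries_bruteforce


def _graph(counts, nodes=None, **kwargs):
    if nodes is None:
        nodes = sorted({t for pair in counts for t in pair})
    return build_graph(counts, nodes, **kwargs)


def _complete_counts(names, self_count=5, cross_count=3):
    counts = {}
    for a in names:
        for b in names:
            counts[(a, b)] = self_count if a == b else cross_count
    return counts


class TestBuildGraphAndAutoregulation:
    def test_empty_counts_gives_edgeless_graph(self):
        g = _graph({}, nodes=["A", "B"])
        assert not g.has_edge("A", "B")
        assert autoregulated_tfs(g) == set()

    def test_edge_min_boundary(self):
        g = _graph({("A", "B"): 2}, nodes=["A", "B"], edge_min=3)
        assert not g.has_edge("A", "B")
        g2 = _graph({("A", "B"): 3}, nodes=["A", "B"], edge_min=3)
        assert g2.has_edge("A", "B")

    def test_nodes_outside_se_associated_set_dropped(self):
        g = build_graph({("A", "Z"): 5, ("Z", "Z"): 9}, ["A"])
        assert g.nodes == ["A"]
        assert g.count("A", "Z") == 0

    @pytest.mark.parametrize(
        "self_count,included", [(3, True), (2, False), (0, False)]
    )
    def test_more_than_two_self_motifs_rule(self, self_count, included):
        g = _graph({("A", "A"): self_count}, nodes=["A"])
        assert (("A" in autoregulated_tfs(g))) is included


class TestEnumerate:
    def test_complete_triangle_emits_all_subsets(self):
        g = _graph(_complete_counts("ABC"))
        circ = enumerate_circuitries(g, min_size=2)
        members = {c.members for c in circ}
        assert members == {("A", "B"), ("A", "C"), ("B", "C"), ("A", "B", "C")}
        maximal = {c.members for c in circ if c.is_maximal}
        assert maximal == {("A", "B", "C")}

    def test_missing_direction_breaks_full_interconnection(self):
        counts = _complete_counts("ABC")
        del counts[("A", "B")]  # a->b gone: no circuitry may contain {A, B}
        circ = enumerate_circuitries(_graph(counts), min_size=2)
        assert all(
            not {"A", "B"} <= set(c.members) for c in circ
        )
        assert {c.members for c in circ} == {("A", "C"), ("B", "C")}

    def test_empty_autoregulated_set_yields_nothing(self):
        g = _graph({("A", "B"): 5, ("B", "A"): 5}, nodes=["A", "B"])
        assert enumerate_circuitries(g) == []

    def test_safety_bound_requires_max_size(self):
        names = [f"T{i:02d}" for i in range(26)]
        g = _graph(_complete_counts(names))
        with pytest.raises(ValueError, match="max_size"):
            enumerate_circuitries(g)
        capped = enumerate_circuitries(g, min_size=2, max_size=2)
        assert len(capped) == len(names) * (len(names) - 1) // 2

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_powerset_oracle_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        names = [f"T{i}" for i in range(n)]
        counts = {}
        for a in names:
            for b in names:
                if a == b:
                    counts[(a, b)] = int(rng.integers(0, 6))
                elif rng.random() < 0.6:
                    counts[(a, b)] = int(rng.integers(1, 4))
        g = _graph(counts, nodes=names)
        got = {frozenset(c.members) for c in enumerate_circuitries(g, min_size=2)}
        edges = {pair for pair, c in counts.items() if c >= 1 and pair[0] != pair[1]}
        expected = circuitries_bruteforce(names, edges, autoregulated_tfs(g))
        assert got == expected

    def test_downward_closure(self):
        g = _graph(_complete_counts("ABCDE"))
        circ = {c.members for c in enumerate_circuitries(g, min_size=2)}
        for members in circ:
            for k in range(2, len(members)):
                for sub in itertools.combinations(members, k):
                    assert tuple(sorted(sub)) in circ


class TestScoring:
    def _toy_universe(self):
        # A,B,C fully interconnected; D connected (both ways) only to A;
        # all four autoregulated
        counts = {}
        for t in "ABCD":
            counts[(t, t)] = 5
        for a, b in itertools.permutations("ABC", 2):
            counts[(a, b)] = 3
        counts[("A", "D")] = 3
        counts[("D", "A")] = 3
        return _graph(counts)

    def test_worked_example_scores_and_ranking(self):
        circ = enumerate_circuitries(self._toy_universe(), min_size=2)
        assert {c.members for c in circ} == {
            ("A", "B"), ("A", "C"), ("B", "C"), ("A", "B", "C"), ("A", "D"),
        }
        ranked = score_circuitries(circ)
        by_members = {c.members: c for c in ranked}
        # occ: A=4, B=3, C=3, D=1 over the five-circuitry universe
        assert by_members[("A", "B", "C")].score == pytest.approx(10 / 3)
        assert by_members[("A", "D")].score == pytest.approx(2.5)
        assert ranked[0].members == ("A", "B", "C")

    def test_single_pair_scores_one(self):
        counts = {("A", "A"): 3, ("B", "B"): 3, ("A", "B"): 1, ("B", "A"): 1}
        ranked = score_circuitries(enumerate_circuitries(_graph(counts)))
        (only,) = ranked
        assert only.members == ("A", "B")
        assert only.score == 1.0

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_symmetric_complete_graph_full_set_on_top(self, k):
        names = [chr(ord("A") + i) for i in range(k)]
        ranked = score_circuitries(
            enumerate_circuitries(_graph(_complete_counts(names)), min_size=2)
        )
        # all members share occ, so same-size circuitries share a score
        by_size: dict[int, set[float]] = {}
        for c in ranked:
            by_size.setdefault(c.size, set()).add(round(c.score, 9))
        assert all(len(v) == 1 for v in by_size.values())
        assert ranked[0].members == tuple(names)
        top_score = max(c.score for c in ranked)
        assert ranked[0].score == pytest.approx(top_score)

    def test_occurrence_recount_reproduces_scores(self, rng):
        names = [f"T{i}" for i in range(8)]
        counts = {}
        for a in names:
            for b in names:
                if a == b:
                    counts[(a, b)] = int(rng.integers(0, 6))
                elif rng.random() < 0.5:
                    counts[(a, b)] = 2
        ranked = score_circuitries(enumerate_circuitries(_graph(counts, nodes=names)))
        for c in ranked:
            occ = sum(
                sum(1 for other in ranked if t in other.members) for t in c.members
            )
            assert c.score == pytest.approx(occ / c.size)


class TestReport:
    def test_empty_universe_writes_header_only(self, tmp_path):
        g = _graph({("A", "A"): 1}, nodes=["A"])
        paths = report_crc(g, [], tmp_path)
        lines = paths["circuitries"].read_text().splitlines()
        assert lines == ["rank\tmembers\tsize\tscore\tis_maximal"]

    def test_report_is_deterministic(self, tmp_path):
        g = self_g = _graph(_complete_counts("ABCD"))
        ranked = score_circuitries(enumerate_circuitries(g))
        p1 = report_crc(g, ranked, tmp_path / "a")
        p2 = report_crc(self_g, ranked, tmp_path / "b")
        assert p1["circuitries"].read_bytes() == p2["circuitries"].read_bytes()
        assert p1["edges"].read_bytes() == p2["edges"].read_bytes()

    def test_synthetic_top_row_is_planted_core(self, pipeline_run, tmp_path):
        result, truth, _ = pipeline_run
        import pandas as pd

        df = pd.read_csv(result.paths["circuitries"], sep="\t")
        assert sorted(df.iloc[0]["members"].split(",")) == sorted(truth.core_tfs)
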