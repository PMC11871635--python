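"""TF→TF regulatory graph, autoregulation rule, circuit enumeration, scoring.

A directed edge a→b means TF a's motif occurs (at least ``edge_min`` times)
in the extended super-enhancer region(s) of TF b. A TF is autoregulated when
its own motif occurs more than ``self_threshold`` (default 2, strict) times
in its own extended SE. A circuitry is a set of autoregulated TFs in which
every ordered pair is an edge — a fully interconnected autoregulatory loop.

All fully interconnected subsets form the circuitry universe; each TF's
occurrence count over that universe feeds the score
score(C) = Σ_{t∈C} occ(t) / |C|. Reported candidates are ranked with maximal
circuitries first (a non-maximal subset is a fragment of a larger loop, not
a candidate core), then by score, size, and members.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "RegulatoryGraph",
    "Circuitry",
    "build_graph",
    "autoregulated_tfs",
    "enumerate_circuitries",
    "score_circuitries",
    "report_crc",
]

SAFETY_NODE_BOUND = 25


@dataclass
class RegulatoryGraph:
    """Motif-support counts between SE-associated TFs."""

    nodes: list[str]
    edge_counts: dict[tuple[str, str], int]
    edge_min: int = 1
    self_threshold: int = 2  # autoregulated iff count(t, t) > self_threshold

    def count(self, source: str, target: str) -> int:
        return self.edge_counts.get((source, target), 0)

    def has_edge(self, source: str, target: str) -> bool:
        return self.count(source, target) >= self.edge_min


@dataclass
class Circuitry:
    """A fully interconnected set of autoregulated TFs."""

    members: tuple[str, ...]  # sorted
    is_maximal: bool = False
    score: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def build_graph(
    hit_counts: Mapping[tuple[str, str], int],
    se_associated_tfs: Sequence[str],
    edge_min: int = 1,
    self_threshold: int = 2,
) -> RegulatoryGraph:
    """Restrict hit counts to SE-associated TFs; missing pairs count 0."""
    nodes = sorted(set(se_associated_tfs))
    node_set = set(nodes)
    counts = {
        (a, b): int(c)
        for (a, b), c in hit_counts.items()
        if a in node_set and b in node_set
    }
    return RegulatoryGraph(
        nodes=nodes,
        edge_counts=counts,
        edge_min=edge_min,
        self_threshold=self_threshold,
    )


def autoregulated_tfs(graph: RegulatoryGraph) -> set[str]:
    """TFs with more than ``self_threshold`` own-motif hits in their own SE."""
    return {t for t in graph.nodes if graph.count(t, t) > graph.self_threshold}


def enumerate_circuitries(
    graph: RegulatoryGraph,
    min_size: int = 2,
    max_size: int | None = None,
) -> list[Circuitry]:
    """Every fully interconnected subset of autoregulated TFs.

    The enumeration is downward-closed: every qualifying subset is emitted,
    not only maximal ones. It runs as a clique enumeration on the
    symmetrized graph (undirected edge iff both directions are edges), which
    is exactly the sets whose ordered pairs are all edges. ``is_maximal``
    flags cliques that cannot be extended by any node.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    auto = sorted(autoregulated_tfs(graph))
    if max_size is None and len(auto) > SAFETY_NODE_BOUND:
        raise ValueError(
            f"{len(auto)} autoregulated TFs would enumerate an exponential "
            f"universe; set max_size to bound circuitry size"
        )
    g = nx.Graph()
    g.add_nodes_from(auto)
    for i, a in enumerate(auto):
        for b in auto[i + 1 :]:
            if graph.has_edge(a, b) and graph.has_edge(b, a):
                g.add_edge(a, b)
    maximal = {frozenset(c) for c in nx.find_cliques(g)} if len(auto) else set()
    out = []
    for clique in nx.enumerate_all_cliques(g):  # yields by increasing size
        if max_size is not None and len(clique) > max_size:
            break
        if len(clique) < min_size:
            continue
        fs = frozenset(clique)
        out.append(Circuitry(members=tuple(sorted(clique)), is_maximal=fs in maximal))
    out.sort(key=lambda c: (c.size, c.members))
    return out


def score_circuitries(
    circuitries: Sequence[Circuitry],
    maximal_only_occurrence: bool = False,
) -> list[Circuitry]:
    """Score and rank circuitries by member occurrence frequency.

    occ(t) = number of enumerated circuitries containing t;
    score(C) = Σ_{t∈C} occ(t) / |C|. With ``maximal_only_occurrence``, occ
    counts only maximal circuitries (sensitivity-analysis mode). Ranking:
    maximal circuitries first, then score descending, size descending,
    lexicographic members.
    """
    universe = (
        [c for c in circuitries if c.is_maximal]
        if maximal_only_occurrence
        else list(circuitries)
    )
    occ: Counter[str] = Counter()
    for c in universe:
        occ.update(c.members)
    scored = []
    for c in circuitries:
        score = sum(occ[t] for t in c.members) / c.size
        scored.append(Circuitry(members=c.members, is_maximal=c.is_maximal, score=score))
    scored.sort(key=lambda c: (not c.is_maximal, -c.score, -c.size, c.members))
    return scored


def report_crc(
    graph: RegulatoryGraph,
    circuitries: Sequence[Circuitry],
    out_dir: str | Path,
    plot: bool = False,
) -> dict[str, Path]:
    """Write ranked circuitries and the edge list; optionally draw the top CRC."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    circ_path = out_dir / "circuitries.tsv"
    rows = [
        {
            "rank": i + 1,
            "members": ",".join(c.members),
            "size": c.size,
            "score": round(c.score, 6) if c.score is not None else "",
            "is_maximal": int(c.is_maximal),
        }
        for i, c in enumerate(circuitries)
    ]
    pd.DataFrame(
        rows, columns=["rank", "members", "size", "score", "is_maximal"]
    ).to_csv(circ_path, sep="\t", index=False)

    edge_path = out_dir / "edges.tsv"
    edge_rows = []
    for a in graph.nodes:
        for b in graph.nodes:
            c = graph.count(a, b)
            edge_rows.append(
                {
                    "source": a,
                    "target": b,
                    "hit_count": c,
                    "is_edge": int(c >= graph.edge_min),
                }
            )
    pd.DataFrame(
        edge_rows, columns=["source", "target", "hit_count", "is_edge"]
    ).to_csv(edge_path, sep="\t", index=False)

    outputs = {"circuitries": circ_path, "edges": edge_path}
    if plot and circuitries:
        outputs["figure"] = _plot_top_circuit(circuitries[0], out_dir)
    return outputs


def _plot_top_circuit(circuit: Circuitry, out_dir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = nx.DiGraph()
    for a in circuit.members:
        for b in circuit.members:
            g.add_edge(a, b)
    fig, ax = plt.subplots(figsize=(5, 5))
    pos = nx.circular_layout(g)
    nx.draw_networkx(
        g, pos, ax=ax, node_color="lightsteelblue", node_size=2200, font_size=9,
        connectionstyle="arc3,rad=0.12",
    )
    ax.set_title(f"Top circuitry (score {circuit.score:.3g})")
    ax.axis("off")
    path = out_dir / "top_circuitry.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
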