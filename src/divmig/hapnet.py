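"""Median-joining haplotype networks (epsilon = 0 by default).

The median-joining algorithm alternates two steps: (1) build the
epsilon-relaxed minimum spanning network (MSN) over the current node set
under Hamming distance — at epsilon 0 this is the union of all minimum
spanning trees; (2) for triples of nodes linked in the MSN, propose the
site-wise majority-consensus median and add medians that reduce the total
network cost (the MST weight of the node set).  When no median helps,
median nodes not needed for any minimal connection are deleted.

Determinism: candidate medians are evaluated in lexicographic sequence
order and the largest cost reduction wins (lexicographically smallest
sequence on ties); at sites where all three triple members differ — where
no majority base exists — the median inherits the base of the
lexicographically first member (a quasi-median simplification).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx

from .popstats import HaplotypeAlignment

__all__ = [
    "HaplotypeNetwork",
    "condense_haplotypes",
    "median_joining_network",
]


class NetworkError(ValueError):
    """Raised for invalid haplotype-network inputs."""


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def condense_haplotypes(
    alignment: HaplotypeAlignment,
) -> tuple[dict[str, int], dict[str, list[str]]]:
    """Group identical sequences; returns (haplotype -> frequency,
    haplotype -> member sequence ids).

    Columns that are gaps in every sequence are removed before matching,
    so alignment padding cannot split otherwise identical haplotypes.
    """
    if len(alignment) == 0:
        raise NetworkError("alignment is empty")
    cols = [
        c
        for c in range(alignment.length)
        if any(seq[c] != "-" for seq in alignment.sequences)
    ]
    freqs: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for seq, ind in zip(alignment.sequences, alignment.individuals):
        key = "".join(seq[c] for c in cols)
        freqs[key] = freqs.get(key, 0) + 1
        members.setdefault(key, []).append(ind)
    return freqs, members


@dataclass
class HaplotypeNetwork:
    """Median-joining network: observed haplotypes plus inferred medians.

    ``graph`` is an undirected networkx graph whose nodes are sequences
    with attributes ``frequency`` (0 for medians) and ``median`` (bool);
    edge weights count differing sites.
    """

    graph: nx.Graph

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["median"]]

    @property
    def medians(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["median"]]

    def total_cost(self) -> int:
        """MST weight over all nodes of the network."""
        mst = nx.minimum_spanning_tree(self.graph, weight="weight")
        return int(sum(d["weight"] for _, _, d in mst.edges(data=True)))

    def sample_size(self) -> int:
        return sum(d["frequency"] for _, d in self.graph.nodes(data=True))

    def to_gml(self, path: str | Path) -> None:
        nx.write_gml(self.graph, str(path))

    def to_edge_tsv(self, path: str | Path) -> None:
        lines = ["node_a\tnode_b\tweight"]
        for u, v, d in sorted(self.graph.edges(data=True)):
            lines.append(f"{u}\t{v}\t{d['weight']}")
        Path(path).write_text("\n".join(lines) + "\n")


def _msn_edges(nodes: list[str], epsilon: int) -> list[tuple[str, str, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    Edge (u, v) of weight w is included iff u and v lie in different
    connected components of the graph restricted to pairs closer than
    w - epsilon; at epsilon 0 this is exactly the union of all MSTs.
    """
    pairs = sorted(
        (_hamming(a, b), a, b) for a, b in combinations(sorted(nodes), 2)
    )
    edges = []
    for w, a, b in pairs:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(
            (x, y) for ww, x, y in pairs if ww <= w - 1 - epsilon
        )
        comp = {n: i for i, c in enumerate(nx.connected_components(g)) for n in c}
        if comp[a] != comp[b]:
            edges.append((a, b, w))
    return edges


def _mst_cost(nodes: list[str]) -> int:
    if len(nodes) < 2:
        return 0
    g = nx.Graph()
    for a, b in combinations(sorted(nodes), 2):
        g.add_edge(a, b, weight=_hamming(a, b))
    mst = nx.minimum_spanning_tree(g, weight="weight")
    return int(sum(d["weight"] for _, _, d in mst.edges(data=True)))


def _majority_median(triple: tuple[str, str, str]) -> str:
    ordered = sorted(triple)
    out = []
    for column in zip(*ordered):
        counts: dict[str, int] = {}
        for base in column:
            counts[base] = counts.get(base, 0) + 1
        best = max(counts.values())
        if best == 1:
            out.append(column[0])  # no majority: inherit first member's base
        else:
            out.append(next(b for b in column if counts[b] == best))
    return "".join(out)


def median_joining_network(
    haplotypes: dict[str, int] | list[str], epsilon: int = 0
) -> HaplotypeNetwork:
    """Build the median-joining network of observed haplotypes.

    ``haplotypes`` maps sequence -> observed frequency (a list counts each
    entry once).  Returns the final network with medians flagged.
    """
    if isinstance(haplotypes, dict):
        freqs = dict(haplotypes)
    else:
        freqs = {}
        for seq in haplotypes:
            freqs[seq] = freqs.get(seq, 0) + 1
    observed = sorted(freqs)
    if len(observed) < 2:
        raise NetworkError("need at least two distinct haplotypes")
    length = len(observed[0])
    if any(len(s) != length for s in observed):
        raise NetworkError("haplotypes must have equal length")

    nodes = list(observed)
    while True:
        edges = _msn_edges(nodes, epsilon)
        linked = nx.Graph()
        linked.add_nodes_from(nodes)
        linked.add_weighted_edges_from(edges)
        current_cost = _mst_cost(nodes)
        candidates = set()
        for u, v, w in sorted(
            (trip for trip in combinations(sorted(nodes), 3)),
            key=lambda t: t,
        ):
            n_links = sum(
                1 for a, b in ((u, v), (u, w), (v, w)) if linked.has_edge(a, b)
            )
            if n_links >= 2:
                med = _majority_median((u, v, w))
                if med not in nodes:
                    candidates.add(med)
        best_med, best_cost = None, current_cost
        for med in sorted(candidates):
            cost = _mst_cost(nodes + [med])
            if cost < best_cost or (cost == best_cost and best_med is not None and med < best_med):
                best_med, best_cost = med, cost
        if best_med is None:
            break
        nodes.append(best_med)

    # delete medians not needed for any minimal connection
    changed = True
    while changed:
        changed = False
        cost_now = _mst_cost(nodes)
        for med in sorted(n for n in nodes if n not in freqs):
            without = [n for n in nodes if n != med]
            if _mst_cost(without) <= cost_now:
                nodes = without
                changed = True
                break

    graph = nx.Graph()
    for node in nodes:
        graph.add_node(node, frequency=freqs.get(node, 0), median=node not in freqs)
    for a, b, w in _msn_edges(nodes, epsilon):
        graph.add_edge(a, b, weight=w)
    return HaplotypeNetwork(graph)
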