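"""Graph and reference-complex containers plus the plain-text readers/writers.

A PPI network is an undirected weighted graph over opaque protein
identifiers.  Edges are stored once per unordered pair; weights are strictly
positive interaction strengths (1.0 when the input file carries no weight
column).  Reference complexes are plain sets of identifiers, one complex per
line, in the style of curated complex catalogues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["PPINetwork", "ComplexSet", "read_edge_list", "read_complexes", "write_clusters"]


@dataclass
class PPINetwork:
    """Undirected weighted protein-interaction graph.

    Parameters
    ----------
    nodes
        Protein identifiers in a fixed order (first-appearance order when
        read from a file).  Row/column indices of every downstream matrix
        refer to this order.
    weights
        Mapping from unordered node pairs (stored as sorted-by-index tuples
        of identifiers) to positive edge weights.
    """

    nodes: list[str]
    weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        index = {v: i for i, v in enumerate(self.nodes)}
        if len(index) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        canon: dict[tuple[str, str], float] = {}
        for (a, b), w in self.weights.items():
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if a not in index or b not in index:
                raise ValueError(f"edge endpoint not in node list: {(a, b)}")
            if not w > 0:
                raise ValueError(f"non-positive weight {w} on edge {(a, b)}")
            key = (a, b) if index[a] < index[b] else (b, a)
            if key in canon and canon[key] != w:
                raise ValueError(f"conflicting weights for edge {key}")
            canon[key] = float(w)
        self.weights = canon
        self._index = index

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def index_of(self, node: str) -> int:
        return self._index[node]

    def has_edge(self, a: str, b: str) -> bool:
        return self._edge_key(a, b) in self.weights

    def weight(self, a: str, b: str, default: float = 0.0) -> float:
        return self.weights.get(self._edge_key(a, b), default)

    def _edge_key(self, a: str, b: str) -> tuple[str, str]:
        return (a, b) if self._index[a] < self._index[b] else (b, a)

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for a, b in self.weights:
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out

    def to_networkx(self) -> nx.Graph:
        """The same graph as a :class:`networkx.Graph` (weight attribute ``weight``)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((a, b, w) for (a, b), w in self.weights.items())
        return g

    def adjacency_lists(self) -> list[list[tuple[int, float]]]:
        """Per-node list of (neighbor index, weight), in node-index space."""
        adj: list[list[tuple[int, float]]] = [[] for _ in self.nodes]
        for (a, b), w in self.weights.items():
            ia, ib = self._index[a], self._index[b]
            adj[ia].append((ib, w))
            adj[ib].append((ia, w))
        return adj


@dataclass
class ComplexSet:
    """An ordered list of protein complexes (sets of identifiers).

    Complexes may overlap and may omit network nodes: curated references
    cover only part of any interaction map.
    """

    complexes: list[set[str]]
    label: str = ""

    def __post_init__(self) -> None:
        for i, c in enumerate(self.complexes):
            if not c:
                raise ValueError(f"complex {i} is empty")
            self.complexes[i] = set(c)

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def as_frozensets(self) -> set[frozenset[str]]:
        return {frozenset(c) for c in self.complexes}


def read_edge_list(path: str | Path, default_weight: float = 1.0) -> PPINetwork:
    """Read a whitespace/tab-separated edge list into a :class:`PPINetwork`.

    Each non-comment line holds ``nodeA nodeB [weight]``.  Duplicate pairs
    collapse to a single edge keeping the maximum weight; two-column lines
    get ``default_weight``; self-loop lines are skipped with a warning.
    Node order is first-appearance order.
    """
    if not default_weight > 0:
        raise ValueError("default_weight must be positive")
    nodes: list[str] = []
    order: dict[str, int] = {}
    weights: dict[tuple[str, str], float] = {}

    def _add_node(v: str) -> None:
        if v not in order:
            order[v] = len(nodes)
            nodes.append(v)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}: line {lineno}: expected 2 or 3 columns, got {len(parts)}")
            a, b = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: bad weight {parts[2]!r}") from exc
            else:
                w = default_weight
            if w <= 0:
                raise ValueError(f"{path}: line {lineno}: weight must be > 0, got {w}")
            _add_node(a)
            if a == b:
                logger.warning("%s: line %d: self-loop on %r skipped", path, lineno, a)
                continue
            _add_node(b)
            key = (a, b) if order[a] < order[b] else (b, a)
            weights[key] = max(w, weights.get(key, 0.0))
    return PPINetwork(nodes=nodes, weights=weights)


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    """Write the network back out as a 3-column TSV (deterministic order)."""
    with open(path, "w") as fh:
        fh.write("# nodeA\tnodeB\tweight\n")
        for (a, b), w in sorted(net.weights.items(), key=lambda kv: (net.index_of(kv[0][0]), net.index_of(kv[0][1]))):
            fh.write(f"{a}\t{b}\t{w:.17g}\n")


def read_complexes(path: str | Path, label: str = "") -> ComplexSet:
    """Read one complex per line (tab-separated IDs); blank lines skipped."""
    complexes: list[set[str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            complexes.append(set(line.split()))
    if not complexes:
        raise ValueError(f"{path}: no complexes")
    return ComplexSet(complexes=complexes, label=label or str(path))


def write_clusters(clusters: ComplexSet | Iterable[Iterable[str]], path: str | Path) -> None:
    """Write clusters one per line, tab-separated, in a deterministic order.

    Clusters are sorted by decreasing size, then by the lexicographically
    smallest member; members within a line are sorted lexicographically.
    """
    sets = [sorted(c) for c in (clusters.complexes if isinstance(clusters, ComplexSet) else clusters)]
    if not sets:
        raise ValueError("no clusters to write")
    sets.sort(key=lambda members: (-len(members), members[0]))
    with open(path, "w") as fh:
        for members in sets:
            fh.write("\t".join(members) + "\n")
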