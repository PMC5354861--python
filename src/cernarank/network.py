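"""Network-based functional similarity: reciprocal shortest-path length.

Biological networks (protein--protein interaction maps and the like)
are loaded as undirected simple graphs: self-loops are removed and the
two directions of an edge are collapsed into one interaction.  The
similarity of two genes is ``1/d`` for unweighted shortest-path
distance ``d``; identical genes score 1, unreachable or absent genes 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = ["BioNetwork", "load_network", "gene_pair_fs_net", "NetworkContext"]


@dataclass
class BioNetwork:
    """Named undirected simple graph over gene ids."""

    name: str
    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], name: str = "network",
        nodes: Iterable[str] = (),
    ) -> "BioNetwork":
        g: nx.Graph = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from((a, b) for a, b in edges if a != b)
        return cls(name, g)


def load_network(path: str | Path, name: str | None = None) -> BioNetwork:
    """Load a two-column TSV edge list into an undirected simple graph.

    Self-loops are dropped and duplicate / reversed edges merged.  A
    malformed row raises with its line number; an empty file yields an
    empty network with a warning.
    """
    net_name = name if name is not None else Path(path).stem
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated gene ids, "
                    f"got {line!r}"
                )
            edges.append((fields[0], fields[1]))
    if not edges:
        warnings.warn(f"{path}: empty edge list", stacklevel=2)
    return BioNetwork.from_edges(edges, name=net_name)


def gene_pair_fs_net(g1: str, g2: str, net: BioNetwork) -> float:
    """1 / shortest-path length; 1.0 for g1 == g2, 0.0 if unreachable."""
    graph = net.graph
    if g1 not in graph or g2 not in graph:
        return 0.0
    if g1 == g2:
        return 1.0
    try:
        d = nx.shortest_path_length(graph, g1, g2)
    except nx.NetworkXNoPath:
        return 0.0
    return 1.0 / d


class NetworkContext:
    """Functional context backed by one biological network.

    Distances are computed by cached single-source breadth-first
    searches, so repeated queries against a small seed set stay cheap.
    """

    def __init__(self, net: BioNetwork, name: str | None = None) -> None:
        self.net = net
        self.name = name if name is not None else net.name
        self._dist: dict[str, dict[str, int]] = {}

    def covers(self, gene_id: str) -> bool:
        return gene_id in self.net.graph

    def _distances_from(self, source: str) -> dict[str, int]:
        d = self._dist.get(source)
        if d is None:
            d = dict(nx.single_source_shortest_path_length(self.net.graph, source))
            self._dist[source] = d
        return d

    def gene_fs(self, g1: str, g2: str) -> float:
        graph = self.net.graph
        if g1 not in graph or g2 not in graph:
            return 0.0
        if g1 == g2:
            return 1.0
        src, dst = (g1, g2) if g1 <= g2 else (g2, g1)
        d = self._distances_from(src).get(dst)
        return 0.0 if d is None else 1.0 / d
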