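"""Follower-graph construction, components, modularity and Louvain communities.

The follower relation is symmetrized: an undirected edge exists between two
users when either follows the other; reciprocal follows collapse to one edge
and self-follows are dropped. Community structure is analyzed on the largest
connected component only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "Partition",
    "build_graph",
    "read_edge_list",
    "largest_component",
    "modularity",
    "louvain",
    "import_partition",
    "export_partition",
]


@dataclass
class Partition:
    """A hard node-to-community assignment with its modularity.

    ``levels`` holds the coarse-to-fine Louvain hierarchy (one membership
    dict per aggregation level, the last one equal to ``membership``); it is
    empty for imported partitions.
    """

    membership: dict[str, int]
    q: float
    levels: list[dict[str, int]] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.membership.items():
            out.setdefault(c, []).append(node)
        return out


def build_graph(edge_list: Iterable[tuple[str, str]]) -> nx.Graph:
    """Simple undirected graph from follower pairs; self-loops dropped,
    reciprocal pairs collapsed."""
    g = nx.Graph()
    for pair in edge_list:
        try:
            u, v = pair
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed edge {pair!r}") from exc
        if not u or not v:
            raise ValueError(f"empty node id in edge {pair!r}")
        if u == v:
            g.add_node(u)
            continue
        g.add_edge(u, v)
    return g


def read_edge_list(path: str | Path) -> nx.Graph:
    """Two-column TSV of user-id pairs."""
    edges = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            edges.append((parts[0], parts[1]))
    return build_graph(edges)


def largest_component(g: nx.Graph) -> tuple[nx.Graph, dict[str, int], dict]:
    """Induced subgraph of the largest connected component plus bookkeeping.

    Returns ``(core, labeling, stats)`` where ``labeling`` maps every node to
    a component id (0 = largest) and ``stats`` reports the core fraction,
    counts of smaller islands and isolated nodes, and core degree summaries.
    Component-size ties go to the component containing the smallest node id.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    comps = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), min(c)),
    )
    labeling = {n: i for i, comp in enumerate(comps) for n in comp}
    core = g.subgraph(comps[0]).copy()
    degrees = [d for _, d in core.degree()]
    islands = sum(1 for c in comps[1:] if len(c) > 1)
    isolated = sum(1 for c in comps[1:] if len(c) == 1)
    stats = {
        "n_nodes": g.number_of_nodes(),
        "core_size": core.number_of_nodes(),
        "core_fraction": core.number_of_nodes() / g.number_of_nodes(),
        "islands": islands,
        "isolated": isolated,
        "mean_degree": sum(degrees) / len(degrees) if degrees else 0.0,
        "max_degree": max(degrees) if degrees else 0,
    }
    return core, labeling, stats


def modularity(g: nx.Graph, membership: Mapping[str, int] | Partition) -> float:
    """Newman modularity Q = Σ_c [e_c/m − (d_c/2m)²].

    ``e_c`` counts intra-community edges, ``d_c`` sums degrees over the
    community, ``m`` is the edge count. The all-in-one partition has Q = 0.
    """
    if isinstance(membership, Partition):
        membership = membership.membership
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    e_c: dict[int, int] = {}
    d_c: dict[int, int] = {}
    for u, v in g.edges():
        if membership[u] == membership[v]:
            e_c[membership[u]] = e_c.get(membership[u], 0) + 1
    for n, deg in g.degree():
        d_c[membership[n]] = d_c.get(membership[n], 0) + deg
    return sum(
        e_c.get(c, 0) / m - (d / (2 * m)) ** 2 for c, d in d_c.items()
    )


def _canonical_membership(comms: Sequence[set]) -> dict[str, int]:
    # deterministic community ids: order communities by their smallest node
    ordered = sorted(comms, key=lambda c: min(map(str, c)))
    return {n: i for i, comm in enumerate(ordered) for n in comm}


def louvain(g: nx.Graph, seed: int = 0, resolution: float = 1.0) -> Partition:
    """Two-phase greedy modularity maximization (Louvain).

    Nodes start in singleton communities; local moves chase the greatest
    modularity gain, then communities are aggregated into a weighted graph
    and the process repeats until no positive gain remains. The returned
    partition carries every hierarchy level; modularity is non-decreasing
    across levels. The node sweep order is randomized by ``seed``; the same
    seed reproduces the same partition.
    """
    if g.number_of_edges() == 0:
        raise ValueError("Louvain requires at least one edge")
    level_parts = list(
        nx.community.louvain_partitions(g, resolution=resolution, seed=seed)
    )
    levels = [_canonical_membership(p) for p in level_parts]
    membership = levels[-1]
    return Partition(membership=membership, q=modularity(g, membership), levels=levels)


def export_partition(p: Partition, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("node\tcommunity\n")
        for node, c in p.membership.items():
            fh.write(f"{node}\t{c}\n")


def import_partition(path: str | Path, g: nx.Graph) -> Partition:
    """Read an externally produced partition (TSV node→community) and attach
    its modularity on ``g``; every node of ``g`` must be covered."""
    membership: dict[str, int] = {}
    with Path(path).open(encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            node, c = line.rstrip("\n").split("\t")
            membership[node] = int(c)
    missing = set(g.nodes()) - set(membership)
    if missing:
        raise ValueError(f"partition missing {len(missing)} node(s), e.g. {sorted(missing)[:3]}")
    return Partition(membership=membership, q=modularity(g, membership))
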