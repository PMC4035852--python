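"""Gene-tree utilities: rooting, the t_diff statistic, species overlap.

A gene tree here is an unrooted weighted tree over gene identifiers. Every
edge induces a bipartition of the leaves and is therefore a candidate root
position; the operations below choose roots either by minimizing the height
of the resulting rooted tree (midpoint-style rooting used before
species-overlap division) or by maximizing t_diff, which measures how well a
bipartition separates the exclusive members of two original clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import networkx as nx

from .core import species_of

__all__ = [
    "GeneTree",
    "Rooting",
    "min_height_root",
    "t_diff",
    "best_root_by_tdiff",
    "species_overlap",
]


class GeneTree:
    """Unrooted weighted tree whose leaves are gene ids.

    Internal nodes carry opaque integer labels. Edge order is the insertion
    order, which makes every tie-break deterministic.
    """

    def __init__(self, species_map: Optional[Mapping[str, str]] = None) -> None:
        self.graph = nx.Graph()
        self.edges: List[Tuple[object, object]] = []
        self._species_map = dict(species_map) if species_map else None
        self._next_internal = 0

    # -- construction -----------------------------------------------------

    def new_internal(self) -> int:
        node = self._next_internal
        self._next_internal += 1
        self.graph.add_node(node, leaf=False)
        return node

    def add_leaf(self, gene_id: str) -> str:
        if gene_id in self.graph:
            raise ValueError(f"duplicate leaf name {gene_id!r}")
        self.graph.add_node(gene_id, leaf=True)
        return gene_id

    def add_edge(self, u, v, length: float) -> None:
        if length < 0:
            length = 0.0  # NJ can emit tiny negative branches; clamp
        self.graph.add_edge(u, v, length=float(length))
        self.edges.append((u, v))

    # -- queries -----------------------------------------------------------

    @property
    def leaves(self) -> List[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("leaf")
        )

    def species(self, gene_id: str) -> str:
        if self._species_map is not None:
            return self._species_map[gene_id]
        return species_of(gene_id)

    def edge_length(self, edge_index: int) -> float:
        u, v = self.edges[edge_index]
        return self.graph.edges[u, v]["length"]

    def bipartition(self, edge_index: int) -> Tuple[FrozenSet[str], FrozenSet[str]]:
        """Leaf sets on the two sides of an edge (u-side first)."""
        u, v = self.edges[edge_index]
        g = self.graph.copy()
        g.remove_edge(u, v)
        side_u = nx.node_connected_component(g, u)
        t1 = frozenset(n for n in side_u if self.graph.nodes[n].get("leaf"))
        t2 = frozenset(self.leaves) - t1
        return t1, t2

    def leaf_distances(self) -> Dict[str, Dict[object, float]]:
        """leaf -> {node: path length} for every node of the tree."""
        out = {}
        for leaf in self.leaves:
            out[leaf] = nx.single_source_dijkstra_path_length(
                self.graph, leaf, weight="length"
            )
        return out

    # -- converters --------------------------------------------------------

    @classmethod
    def from_skbio(cls, node, species_map=None) -> "GeneTree":
        tree = cls(species_map)

        def walk(snode):
            if snode.is_tip():
                return tree.add_leaf(snode.name)
            children = list(snode.children)
            if len(children) == 1:  # suppress unifurcation
                child = walk(children[0])
                return child
            me = tree.new_internal()
            for ch in children:
                sub = walk(ch)
                tree.add_edge(me, sub, ch.length or 0.0)
            return me

        walk(node)
        return tree

    @classmethod
    def from_dendropy(cls, dtree, species_map=None) -> "GeneTree":
        tree = cls(species_map)
        mapping = {}
        for node in dtree.preorder_node_iter():
            if node.is_leaf():
                mapping[node] = tree.add_leaf(node.taxon.label)
            else:
                mapping[node] = tree.new_internal()
            if node.parent_node is not None:
                tree.add_edge(
                    mapping[node.parent_node],
                    mapping[node],
                    node.edge.length or 0.0,
                )
        # a rooted bifurcating input leaves a degree-2 root; splice it out
        for node in list(tree.graph.nodes):
            if (
                not tree.graph.nodes[node].get("leaf")
                and tree.graph.degree(node) == 2
            ):
                (a, da), (b, db) = (
                    (nbr, tree.graph.edges[node, nbr]["length"])
                    for nbr in tree.graph.neighbors(node)
                )
                tree.graph.remove_node(node)
                tree.edges = [
                    e for e in tree.edges if node not in e
                ]
                tree.add_edge(a, b, da + db)
        return tree


@dataclass(frozen=True)
class Rooting:
    """A chosen root position: an edge, a position along it, the split."""

    edge_index: int
    position: float  # fraction along the edge from its first endpoint
    subtrees: Tuple[FrozenSet[str], FrozenSet[str]]
    height: float


def min_height_root(tree: GeneTree) -> Rooting:
    """Root position minimizing the height of the rooted tree.

    For each edge (u, v, L) with deepest leaf distances h_u, h_v on the two
    sides, the height of a root at distance x from u is
    max(h_u + x, h_v + L - x), minimized at x* = clamp((h_v - h_u + L)/2).
    The global optimum is the midpoint of the tree diameter path; edges are
    scanned exhaustively and ties resolved by edge index.
    """
    leaves = tree.leaves
    if len(leaves) < 2:
        raise ValueError("rooting needs at least 2 leaves")
    dist = tree.leaf_distances()
    best: Optional[Tuple[float, int, float]] = None
    parts = []
    for ei, (u, v) in enumerate(tree.edges):
        length = tree.edge_length(ei)
        t1, t2 = tree.bipartition(ei)
        parts.append((t1, t2))
        h_u = max(dist[leaf][u] for leaf in t1) if t1 else 0.0
        h_v = max(dist[leaf][v] for leaf in t2) if t2 else 0.0
        x = min(max((h_v - h_u + length) / 2.0, 0.0), length)
        height = max(h_u + x, h_v + length - x)
        if best is None or height < best[0] - 1e-12:
            best = (height, ei, x)
    height, ei, x = best  # type: ignore[misc]
    length = tree.edge_length(ei)
    position = x / length if length > 0 else 0.0
    return Rooting(ei, position, parts[ei], height)


def t_diff(
    g1: Iterable[str],
    g2: Iterable[str],
    g12: Iterable[str],
    t1: Iterable[str],
    t2: Iterable[str],
) -> int:
    """Separation statistic of a tree bipartition (t1, t2) w.r.t. two
    original clusters.

    g1/g2 are the genes exclusive to each original cluster, g12 the genes
    in both (split genes, i.e. fused architectures). Genes in both clusters
    count as support whichever side they fall on, hence the absolute value
    on the g12 term.
    """
    g1, g2, g12 = set(g1), set(g2), set(g12)
    t1, t2 = set(t1), set(t2)
    return (
        len(g1 & t1)
        + len(g2 & t2)
        - len(g1 & t2)
        - len(g2 & t1)
        + abs(len(g12 & t1) - len(g12 & t2))
    )


def best_root_by_tdiff(
    tree: GeneTree,
    g1: Iterable[str],
    g2: Iterable[str],
    g12: Iterable[str],
) -> Rooting:
    """Candidate root (edge) maximizing t_diff.

    Each edge's bipartition is evaluated in the orientation maximizing
    t_diff; ties are broken by the longest edge, then by edge index.
    """
    leaves = tree.leaves
    if len(leaves) < 3:
        raise ValueError("best_root_by_tdiff needs at least 3 leaves")
    g1, g2, g12 = set(g1), set(g2), set(g12)
    best = None
    for ei in range(len(tree.edges)):
        t1, t2 = tree.bipartition(ei)
        score = max(t_diff(g1, g2, g12, t1, t2), t_diff(g1, g2, g12, t2, t1))
        length = tree.edge_length(ei)
        key = (score, length, -ei)
        if best is None or key > best[0]:
            # orient so t1 is the side matching g1 best
            if t_diff(g1, g2, g12, t1, t2) >= t_diff(g1, g2, g12, t2, t1):
                parts = (t1, t2)
            else:
                parts = (t2, t1)
            best = (key, ei, parts)
    _, ei, parts = best  # type: ignore[misc]
    return Rooting(ei, 0.5, parts, float("nan"))


def species_overlap(
    t1: Iterable[str], t2: Iterable[str], species_map=None
) -> float:
    """Jaccard index of the species sets of two gene groups."""
    t1, t2 = list(t1), list(t2)
    if not t1 or not t2:
        raise ValueError("species_overlap needs two non-empty groups")

    def sp(g):
        if species_map is None:
            return species_of(g)
        if callable(species_map):
            return species_map(g)
        return species_map[g]

    s1 = {sp(g) for g in t1}
    s2 = {sp(g) for g in t2}
    return len(s1 & s2) / len(s1 | s2)
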