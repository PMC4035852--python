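"""Cluster-correspondence evaluation and alignment conservation coloring.

Two domain-level clusterings over a shared gene universe are compared by a
bipartite overlap graph: clusters C_i and D_j are connected when some gene
has fragments in both with at least one residue in common. A pair whose two
endpoints both have degree one is a one-to-one relationship; their count
N^1to1 measures agreement. Moderate agreement is measured by the mean
overlap ratio r̄_over, the average over all overlapping fragment pairs of
r_over = |c ∩ d| / max(|c|, |d|).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

from .core import AlignmentMatrix, ClusteringState, Fragment, ScoreParams

__all__ = [
    "OverlapGraph",
    "CorrespondenceReport",
    "find_correspondences",
    "count_one_to_one",
    "overlap_ratio",
    "mean_overlap",
    "compare",
    "classify_inclusion",
    "conservation_color",
    "render_html",
]


@dataclass
class OverlapGraph:
    """Bipartite cluster-overlap graph with per-fragment-pair overlap ratios."""

    #: (cluster_A, cluster_B) -> [(gene, r_over), ...]
    edges: Dict[Tuple[str, str], List[Tuple[str, float]]] = field(
        default_factory=dict
    )

    def degree_a(self) -> Dict[str, int]:
        deg: Dict[str, int] = {}
        for a, _ in self.edges:
            deg[a] = deg.get(a, 0) + 1
        return deg

    def degree_b(self) -> Dict[str, int]:
        deg: Dict[str, int] = {}
        for _, b in self.edges:
            deg[b] = deg.get(b, 0) + 1
        return deg


@dataclass
class CorrespondenceReport:
    overlap_pairs: List[Tuple[str, str, str, float]]
    one_to_one_pairs: List[Tuple[str, str]]
    n_one_to_one: int
    mean_overlap: float


def overlap_ratio(frag_c: Fragment, frag_d: Fragment) -> float:
    """r_over: residue overlap divided by the longer fragment's length."""
    ov = frag_c.overlap(frag_d)  # raises on different genes
    return ov / max(frag_c.length, frag_d.length)


def find_correspondences(
    clustering_a: ClusteringState, clustering_b: ClusteringState
) -> OverlapGraph:
    """Overlap graph: an edge wherever fragments of one gene share >= 1
    residue between a cluster of A and a cluster of B."""
    graph = OverlapGraph()
    index_b = clustering_b.gene_index()
    for gene, entries_a in sorted(clustering_a.gene_index().items()):
        for cid_a, frag_a in entries_a:
            for cid_b, frag_b in index_b.get(gene, ()):
                if frag_a.overlap(frag_b) >= 1:
                    graph.edges.setdefault((cid_a, cid_b), []).append(
                        (gene, overlap_ratio(frag_a, frag_b))
                    )
    return graph


def count_one_to_one(graph: OverlapGraph) -> Tuple[int, List[Tuple[str, str]]]:
    """Edges whose both endpoints touch nothing else."""
    deg_a = graph.degree_a()
    deg_b = graph.degree_b()
    pairs = sorted(
        (a, b)
        for a, b in graph.edges
        if deg_a[a] == 1 and deg_b[b] == 1
    )
    return len(pairs), pairs


def mean_overlap(graph: OverlapGraph) -> float:
    """r̄_over: mean of r_over over all overlapping fragment pairs."""
    values = [r for pairs in graph.edges.values() for _, r in pairs]
    if not values:
        raise ValueError("no overlapping fragments")
    return sum(values) / len(values)


def compare(
    clustering_a: ClusteringState, clustering_b: ClusteringState
) -> CorrespondenceReport:
    graph = find_correspondences(clustering_a, clustering_b)
    n, pairs = count_one_to_one(graph)
    overlap_pairs = sorted(
        (a, b, gene, r)
        for (a, b), lst in graph.edges.items()
        for gene, r in lst
    )
    mo = mean_overlap(graph) if graph.edges else float("nan")
    return CorrespondenceReport(overlap_pairs, pairs, n, mo)


def classify_inclusion(
    graph: OverlapGraph,
    clustering_a: ClusteringState,
    clustering_b: ClusteringState,
    containment: float = 0.8,
) -> Dict[Tuple[str, str], str]:
    """Heuristic relationship classes for overlapping cluster pairs.

    A reconstruction, not a published definition: for each overlapping
    fragment pair the smaller fragment counts as contained when at least
    `containment` of it lies inside the larger one; a cluster pair is
    "equivalent" when containment holds in both directions for every shared
    gene, "supergroup"/"subgroup" when the A cluster consistently contains /
    is contained by the B cluster, else "overlap".
    """
    out: Dict[Tuple[str, str], str] = {}
    for (a, b), genes in sorted(graph.edges.items()):
        a_holds = b_holds = True
        for gene, _ in genes:
            frag_a = clustering_a.clusters[a].members[gene]
            frag_b = clustering_b.clusters[b].members[gene]
            ov = frag_a.overlap(frag_b)
            if ov < containment * frag_b.length:
                a_holds = False  # A does not contain B's fragment
            if ov < containment * frag_a.length:
                b_holds = False
        if a_holds and b_holds:
            out[(a, b)] = "equivalent"
        elif a_holds:
            out[(a, b)] = "supergroup"
        elif b_holds:
            out[(a, b)] = "subgroup"
        else:
            out[(a, b)] = "overlap"
    return out


# ---------------------------------------------------------------------------
# Conservation coloring
# ---------------------------------------------------------------------------

_CLASSES = ("red", "yellow", "cyan")


def conservation_color(
    alignment: AlignmentMatrix, params: ScoreParams = ScoreParams()
) -> List[List[str]]:
    """Per-cell color class from the column conservation rate p_cons.

    p_cons is the frequency of the modal residue among the column's non-gap
    cells (all-gap columns rate 0). With the default cutoffs: red for
    p_cons >= 70%, yellow for 70% > p_cons >= 50%, cyan for 50% > p_cons
    >= 30%, no class below. Gap cells carry no class.
    """
    hi, mid, lo = params.conservation_cutoffs
    colors = [["" for _ in range(alignment.n_pos)] for _ in range(alignment.n_seq)]
    for j in range(alignment.n_pos):
        col = alignment.codes[:, j]
        residues = col[col != 0]
        if residues.size == 0:
            continue
        counts: Dict[int, int] = {}
        for c in residues:
            counts[int(c)] = counts.get(int(c), 0) + 1
        p_cons = max(counts.values()) / residues.size
        if p_cons >= hi:
            cls = "red"
        elif p_cons >= mid:
            cls = "yellow"
        elif p_cons >= lo:
            cls = "cyan"
        else:
            cls = ""
        if not cls:
            continue
        for i in range(alignment.n_seq):
            if col[i] != 0:
                colors[i][j] = cls
    return colors


def render_html(
    alignment: AlignmentMatrix,
    state: ClusteringState = None,
    params: ScoreParams = ScoreParams(),
) -> str:
    """Monospace HTML rendering of the alignment with conservation colors
    and (optionally) domain extents underlined per cluster."""
    colors = conservation_color(alignment, params)
    styles = {
        "red": "background:#ff9999",
        "yellow": "background:#ffff99",
        "cyan": "background:#99ffff",
    }
    domain_cols: Dict[int, Set[int]] = {}
    if state is not None:
        from .core import indicator_for_fragments

        frags = [
            f
            for c in state.clusters.values()
            for f in c.members.values()
            if f.gene_id in alignment.row_ids
        ]
        x = indicator_for_fragments(alignment, frags)
        for i in range(alignment.n_seq):
            domain_cols[i] = set(map(int, x[i].nonzero()[0]))
    lines = [
        "<html><body><pre style='font-family:monospace'>",
    ]
    width = max((len(g) for g in alignment.row_ids), default=0)
    for i, gene in enumerate(alignment.row_ids):
        cells = []
        for j, ch in enumerate(alignment.rows[i]):
            style = styles.get(colors[i][j], "")
            if state is not None and j in domain_cols.get(i, ()):
                style += ";text-decoration:underline"
            if style:
                cells.append(f"<span style='{style}'>{ch}</span>")
            else:
                cells.append(ch)
        lines.append(f"{gene.ljust(width)} " + "".join(cells))
    lines.append("</pre></body></html>")
    return "\n".join(lines)
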