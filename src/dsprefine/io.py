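"""Readers and writers for the on-disk formats the pipeline touches.

Cluster file dialect
--------------------
Plain text, one member fragment per line, tab- or space-delimited::

    cluster_id  gene_id  begin  end

Coordinates are 1-based inclusive (converted to the internal 0-based
half-open convention on read). Lines starting with ``#`` and blank lines
are ignored. Gene ids follow the ``org:locus`` convention; the species id
is the prefix before the first colon.

On read, per-gene boundary gaps or overlaps of at most ``SNAP_TOLERANCE``
residues between consecutive fragments are snapped to a single shared
boundary (clustering tools routinely emit one-off coordinates); every
adjustment is recorded. Overlaps beyond the tolerance are an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AlignmentMatrix,
    Cluster,
    ClusteringState,
    Fragment,
    ScoreParams,
    normalize_sequence,
)
from .trees import GeneTree

logger = logging.getLogger("dsprefine")

#: max residue gap/overlap between consecutive fragments snapped on read
SNAP_TOLERANCE = 2


@dataclass
class SnapAdjustment:
    gene_id: str
    old_boundary: Tuple[int, int]  # (end of left frag, begin of right), 0-based
    new_boundary: int


def read_clusters(path) -> ClusteringState:
    state, _ = read_clusters_with_adjustments(path)
    return state


def read_clusters_with_adjustments(
    path,
) -> Tuple[ClusteringState, List[SnapAdjustment]]:
    """Parse a cluster file; returns the state and the boundary snaps applied."""
    raw: Dict[str, List[Fragment]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 fields "
                    f"(cluster_id gene_id begin end), got {len(fields)}"
                )
            cid, gene, b, e = fields
            try:
                begin1, end1 = int(b), int(e)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates")
            if begin1 < 1 or end1 < begin1:
                raise ValueError(
                    f"{path}:{lineno}: bad interval {begin1}..{end1}"
                )
            # 1-based inclusive -> 0-based half-open
            raw.setdefault(cid, []).append(Fragment(gene, begin1 - 1, end1))

    adjustments = _snap_boundaries(raw)
    state = ClusteringState()
    for cid in sorted(raw):
        cluster = Cluster(cid)
        for frag in sorted(raw[cid]):
            cluster.add(frag)
        state.add_cluster(cluster)
    _check_no_overlaps(state, path)
    return state, adjustments


def _snap_boundaries(raw: Dict[str, List[Fragment]]) -> List[SnapAdjustment]:
    by_gene: Dict[str, List[Tuple[str, int]]] = {}
    for cid, frags in raw.items():
        for i, f in enumerate(frags):
            by_gene.setdefault(f.gene_id, []).append((cid, i))
    adjustments: List[SnapAdjustment] = []
    for gene in sorted(by_gene):
        entries = sorted(
            by_gene[gene], key=lambda ci: (raw[ci[0]][ci[1]].begin, ci[0])
        )
        for (ca, ia), (cb, ib) in zip(entries, entries[1:]):
            left, right = raw[ca][ia], raw[cb][ib]
            delta = right.begin - left.end  # >0 gap, <0 overlap
            if delta == 0 or abs(delta) > SNAP_TOLERANCE:
                continue
            boundary = (left.end + right.begin + 1) // 2
            boundary = max(left.begin + 1, min(boundary, right.end - 1))
            adjustments.append(
                SnapAdjustment(gene, (left.end, right.begin), boundary)
            )
            raw[ca][ia] = Fragment(gene, left.begin, boundary)
            raw[cb][ib] = Fragment(gene, boundary, right.end)
            logger.debug(
                "snapped boundary of %s: %s -> %d",
                gene,
                (left.end, right.begin),
                boundary,
            )
    return adjustments


def _check_no_overlaps(state: ClusteringState, path) -> None:
    for gene, entries in state.gene_index().items():
        frags = [f for _, f in entries]
        for a, b in zip(frags, frags[1:]):
            if a.overlap(b) > 0:
                raise ValueError(
                    f"{path}: fragments of gene {gene} overlap beyond the "
                    f"snap tolerance: [{a.begin},{a.end}) vs [{b.begin},{b.end})"
                )


def write_clusters(state: ClusteringState, path) -> None:
    """Write the dialect above, deterministically ordered."""
    with open(path, "w") as fh:
        for cid in state.cluster_ids():
            cluster = state.clusters[cid]
            for gene in cluster.gene_ids:
                frag = cluster.members[gene]
                fh.write(f"{cid}\t{gene}\t{frag.begin + 1}\t{frag.end}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seqs[k]), id=k, description="") for k in sorted(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_aligned_fasta(path) -> AlignmentMatrix:
    ids: List[str] = []
    rows: List[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        ids.append(rec.id)
        rows.append(normalize_sequence(str(rec.seq)))
    return AlignmentMatrix(rows, ids)


def write_aligned_fasta(alignment: AlignmentMatrix, path) -> None:
    with open(path, "w") as fh:
        for gene, row in zip(alignment.row_ids, alignment.rows):
            fh.write(f">{gene}\n{row}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path) -> GeneTree:
    dtree = dendropy.Tree.get(path=str(path), schema="newick")
    labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate leaf labels")
    return GeneTree.from_dendropy(dtree)


def parse_newick(text: str) -> GeneTree:
    dtree = dendropy.Tree.get(data=text, schema="newick")
    return GeneTree.from_dendropy(dtree)


def write_newick(tree: GeneTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


def tree_to_newick(tree: GeneTree) -> str:
    """Serialize a GeneTree, quoting labels that contain newick metachars."""
    graph = tree.graph
    nodes = list(graph.nodes)
    if not nodes:
        return ";"
    leaves = tree.leaves
    if len(leaves) == 1:
        return f"({_quote(leaves[0])}:0.0);"
    internals = sorted(
        (n for n in nodes if not graph.nodes[n].get("leaf")), key=str
    )
    if not internals:
        # two leaves joined by one edge: emit a midpoint root (spliced back
        # into a single edge on read)
        a, b = leaves
        half = graph.edges[a, b]["length"] / 2.0
        return f"({_quote(a)}:{half:g},{_quote(b)}:{half:g});"
    # root at an arbitrary but deterministic internal node
    root = internals[0]

    def render(node, parent) -> str:
        children = [n for n in graph.neighbors(node) if n != parent]
        children.sort(key=str)
        if not children:
            return _quote(node)
        inner = ",".join(
            f"{render(ch, node)}:{graph.edges[node, ch]['length']:g}"
            for ch in children
        )
        return f"({inner})"

    return render(root, None) + ";"


def _quote(label: str) -> str:
    if any(c in label for c in ":,();[] '\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def read_config(path) -> Dict[str, str]:
    """Plain ``key = value`` config file; '#' starts a comment."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def params_from_config(cfg: Mapping[str, str]) -> ScoreParams:
    kwargs = {}
    if "gap_open" in cfg:
        kwargs["gap_open"] = float(cfg["gap_open"])
    if "gap_ext" in cfg:
        kwargs["gap_ext"] = float(cfg["gap_ext"])
    if "score_matrix" in cfg:
        kwargs["score_matrix_name"] = cfg["score_matrix"]
    if "merge_threshold" in cfg:
        kwargs["merge_threshold"] = float(cfg["merge_threshold"])
    if "species_overlap_threshold" in cfg:
        kwargs["species_overlap_threshold"] = float(
            cfg["species_overlap_threshold"]
        )
    if "conservation_cutoffs" in cfg:
        parts = [float(v) for v in cfg["conservation_cutoffs"].split(",")]
        kwargs["conservation_cutoffs"] = tuple(parts)
    return ScoreParams(**kwargs)
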