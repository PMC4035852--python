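"""Shared data model: sequences, alignments, domain indicators, clusters.

Coordinate conventions
----------------------
All residue intervals are 0-based half-open ``[begin, end)`` internally.
The on-disk cluster dialect (module :mod:`dsprefine.io`) is 1-based inclusive;
conversion happens only there.

Gene identifiers follow the ``org:locus`` convention common in microbial
comparative genomics (e.g. ``eco:b0001``); the species identifier is the
prefix before the first colon.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.Align import substitution_matrices

GAP = "-"
#: input gap spellings normalized to GAP
_GAP_CHARS = {"-", "."}

#: residue alphabet used for integer encoding (gap is code 0)
ALPHABET = GAP + "ACDEFGHIKLMNPQRSTVWYBZXUO*"
_CODE: Dict[str, int] = {c: i for i, c in enumerate(ALPHABET)}


def is_residue(symbol: str) -> bool:
    """b(a): True iff the symbol denotes an amino acid (anything but a gap)."""
    return symbol not in _GAP_CHARS


def normalize_sequence(seq: str) -> str:
    out = []
    for c in seq.upper():
        out.append(GAP if c in _GAP_CHARS else c)
    return "".join(out)


def encode(seq: str) -> np.ndarray:
    """Encode a (possibly gapped) sequence as int8 codes over ALPHABET.

    Unrecognized symbols map to 'X'.
    """
    x_code = _CODE["X"]
    return np.array(
        [_CODE.get(c, x_code) for c in normalize_sequence(seq)], dtype=np.int8
    )


def species_of(gene_id: str) -> str:
    return gene_id.split(":", 1)[0]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreParams:
    """Scoring and refinement parameters.

    Attributes
    ----------
    gap_open:
        G_open, charged once per open gap run (score units, >= 0).
    gap_ext:
        G_ext, charged per gap column inside a domain (score units, >= 0).
    score_matrix_name:
        Name of a standard amino-acid substitution matrix (s_mat).
    merge_threshold:
        S_delta, the normalized score-change threshold above which two
        adjacent clusters are merged. Negative by default: a split must earn
        a sufficient score gain to be kept.
    species_overlap_threshold:
        R_sp in [0, 1]; a cluster is divided when the Jaccard overlap of the
        species sets of the two root subtrees reaches this value.
    conservation_cutoffs:
        Column conservation-rate (p_cons) class boundaries for rendering,
        highest first: red / yellow / cyan.
    """

    gap_open: float = 10.0
    gap_ext: float = 0.5
    score_matrix_name: str = "BLOSUM45"
    merge_threshold: float = -0.05
    species_overlap_threshold: float = 0.5
    conservation_cutoffs: Tuple[float, float, float] = (0.70, 0.50, 0.30)

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_ext < 0:
            raise ValueError("gap penalties must be non-negative")
        if not 0.0 <= self.species_overlap_threshold <= 1.0:
            raise ValueError("species_overlap_threshold must lie in [0, 1]")
        if list(self.conservation_cutoffs) != sorted(
            self.conservation_cutoffs, reverse=True
        ):
            raise ValueError("conservation_cutoffs must be decreasing")


def load_score_matrix(name_or_path: str) -> np.ndarray:
    """Return a dense |ALPHABET| x |ALPHABET| score table.

    `name_or_path` is either the name of a matrix shipped with Biopython
    (e.g. "BLOSUM45") or a path to an NCBI-format matrix text file.
    Symbol pairs absent from the matrix score 0; gap rows/columns are 0
    (gap treatment is handled by the DSP gap terms, not by s_mat).
    """
    try:
        mat = substitution_matrices.load(name_or_path)
    except FileNotFoundError:
        mat = substitution_matrices.read(name_or_path)
    n = len(ALPHABET)
    table = np.zeros((n, n), dtype=np.float64)
    alpha = mat.alphabet
    for i, a in enumerate(ALPHABET):
        if a == GAP or a not in alpha:
            continue
        for j, b in enumerate(ALPHABET):
            if b == GAP or b not in alpha:
                continue
            table[i, j] = float(mat[a, b])
    return table


# ---------------------------------------------------------------------------
# Fragments, clusters, clustering state
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Fragment:
    """A contiguous residue interval of one protein, 0-based half-open."""

    gene_id: str
    begin: int
    end: int

    def __post_init__(self) -> None:
        if not self.begin < self.end:
            raise ValueError(
                f"empty fragment {self.gene_id}[{self.begin},{self.end})"
            )
        if self.begin < 0:
            raise ValueError(f"negative begin for {self.gene_id}")

    @property
    def species_id(self) -> str:
        return species_of(self.gene_id)

    @property
    def length(self) -> int:
        return self.end - self.begin

    def overlap(self, other: "Fragment") -> int:
        if self.gene_id != other.gene_id:
            raise ValueError("fragments of different genes do not overlap")
        return max(0, min(self.end, other.end) - max(self.begin, other.begin))


@dataclass
class Cluster:
    """A domain-level ortholog cluster: at most one fragment per gene."""

    cluster_id: str
    members: Dict[str, Fragment] = field(default_factory=dict)

    def add(self, frag: Fragment) -> None:
        if frag.gene_id in self.members:
            raise ValueError(
                f"gene {frag.gene_id} already in cluster {self.cluster_id}"
            )
        self.members[frag.gene_id] = frag

    @property
    def gene_ids(self) -> List[str]:
        return sorted(self.members)

    @property
    def species_ids(self) -> Set[str]:
        return {species_of(g) for g in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def copy(self) -> "Cluster":
        return Cluster(self.cluster_id, dict(self.members))


class ClusteringState:
    """The full set of clusters of one domain-level clustering."""

    def __init__(self, clusters: Iterable[Cluster] = ()) -> None:
        self.clusters: Dict[str, Cluster] = {}
        for c in clusters:
            self.add_cluster(c)

    def add_cluster(self, cluster: Cluster) -> None:
        if cluster.cluster_id in self.clusters:
            raise ValueError(f"duplicate cluster id {cluster.cluster_id}")
        self.clusters[cluster.cluster_id] = cluster

    def remove_cluster(self, cluster_id: str) -> None:
        del self.clusters[cluster_id]

    def cluster_ids(self) -> List[str]:
        return sorted(self.clusters)

    def gene_index(self) -> Dict[str, List[Tuple[str, Fragment]]]:
        """gene_id -> [(cluster_id, fragment)] sorted by fragment begin.

        Rebuilt from the clusters on every call, so it is consistent by
        construction.
        """
        index: Dict[str, List[Tuple[str, Fragment]]] = {}
        for cid in self.cluster_ids():
            for frag in self.clusters[cid].members.values():
                index.setdefault(frag.gene_id, []).append((cid, frag))
        for entries in index.values():
            entries.sort(key=lambda cf: (cf[1].begin, cf[0]))
        return index

    def copy(self) -> "ClusteringState":
        return ClusteringState(c.copy() for c in self.clusters.values())

    def total_residues(self) -> int:
        return sum(
            f.length for c in self.clusters.values() for f in c.members.values()
        )

    def __len__(self) -> int:
        return len(self.clusters)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClusteringState):
            return NotImplemented
        mine = {cid: dict(c.members) for cid, c in self.clusters.items()}
        theirs = {cid: dict(c.members) for cid, c in other.clusters.items()}
        return mine == theirs


def validate_state(
    state: ClusteringState, sequences: Optional[Mapping[str, str]] = None
) -> List[str]:
    """Diagnose invariant violations; an empty list means the state is valid.

    Checks: per-gene fragments across clusters are non-overlapping; fragments
    fit inside the protein when `sequences` is given.
    """
    violations: List[str] = []
    for gene, entries in sorted(state.gene_index().items()):
        frags = [f for _, f in entries]
        for a, b in zip(frags, frags[1:]):
            if a.overlap(b) > 0:
                violations.append(
                    f"gene {gene}: overlapping fragments "
                    f"[{a.begin},{a.end}) and [{b.begin},{b.end})"
                )
        if sequences is not None and gene in sequences:
            n = len(sequences[gene])
            for f in frags:
                if f.end > n:
                    violations.append(
                        f"gene {gene}: fragment [{f.begin},{f.end}) exceeds "
                        f"protein length {n}"
                    )
        elif sequences is not None:
            violations.append(f"gene {gene}: no sequence provided")
    return violations


# ---------------------------------------------------------------------------
# Alignments and domain matrices
# ---------------------------------------------------------------------------


class AlignmentMatrix:
    """A multiple alignment A = (a_ij): N_seq rows over N_pos columns."""

    def __init__(self, rows: Sequence[str], row_ids: Sequence[str]) -> None:
        rows = [normalize_sequence(r) for r in rows]
        if len(rows) != len(row_ids):
            raise ValueError("row/id count mismatch")
        if len(set(row_ids)) != len(row_ids):
            raise ValueError("duplicate row ids in alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal aligned row lengths: {sorted(lengths)}")
        self.row_ids: List[str] = list(row_ids)
        self.rows: List[str] = rows
        self.n_seq = len(rows)
        self.n_pos = len(rows[0]) if rows else 0
        self.codes = (
            np.vstack([encode(r) for r in rows])
            if rows
            else np.zeros((0, 0), dtype=np.int8)
        )
        #: residue mask b(a_ij)
        self.residue_mask = self.codes != 0
        self._row_of = {g: i for i, g in enumerate(self.row_ids)}

    @property
    def n_aa(self) -> int:
        """N_aa: total number of amino acids in the alignment."""
        return int(self.residue_mask.sum())

    def row_index(self, gene_id: str) -> int:
        try:
            return self._row_of[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id} is not a row of the alignment")

    def ungapped(self, gene_id: str) -> str:
        return self.rows[self.row_index(gene_id)].replace(GAP, "")

    def residue_columns(self, row: int) -> np.ndarray:
        """Alignment columns of the row's residues, in sequence order."""
        return np.flatnonzero(self.residue_mask[row])


def project_fragment(
    alignment: AlignmentMatrix, row: int, begin: int, end: int
) -> np.ndarray:
    """Columns of `alignment` holding residues `[begin, end)` of row `row`.

    Gap columns inside the spanned region are not returned; only residue
    cells are (the domain-matrix builder marks internal gap cells
    separately).
    """
    cols = alignment.residue_columns(row)
    if begin < 0 or end > cols.size or begin >= end:
        gene = alignment.row_ids[row]
        raise ValueError(
            f"interval [{begin},{end}) out of range for {gene} "
            f"(length {cols.size})"
        )
    return cols[begin:end]


class DomainMatrix:
    """Indicator matrix D = (d_ij) of the cells belonging to one domain."""

    def __init__(self, parent: AlignmentMatrix, cells: np.ndarray) -> None:
        if cells.shape != (parent.n_seq, parent.n_pos):
            raise ValueError("domain matrix shape differs from its alignment")
        self.parent = parent
        self.cells = cells.astype(np.uint8)

    @property
    def in_domain_residues(self) -> np.ndarray:
        """b(a_ij) * d_ij as a boolean matrix (the quantity DSP scores use)."""
        return self.cells.astype(bool) & self.parent.residue_mask

    def member_rows(self) -> np.ndarray:
        return np.flatnonzero(self.in_domain_residues.any(axis=1))

    def fragment_of_row(self, row: int) -> Optional[Tuple[int, int]]:
        """Residue interval [begin, end) covered on `row`, or None."""
        marked = self.in_domain_residues[row]
        if not marked.any():
            return None
        cols = self.parent.residue_columns(row)
        pos = np.flatnonzero(marked[cols])
        return int(pos[0]), int(pos[-1]) + 1


def indicator_for_fragments(
    alignment: AlignmentMatrix, fragments: Iterable[Fragment]
) -> np.ndarray:
    """Boolean N_seq x N_pos matrix of in-domain *residue* cells."""
    x = np.zeros((alignment.n_seq, alignment.n_pos), dtype=bool)
    for frag in fragments:
        row = alignment.row_index(frag.gene_id)
        cols = project_fragment(alignment, row, frag.begin, frag.end)
        x[row, cols] = True
    return x


def build_domain_matrix(
    alignment: AlignmentMatrix, cluster: Cluster
) -> DomainMatrix:
    """Build D for `cluster` on `alignment`.

    Residue cells of each member fragment are marked, and so are gap cells
    lying strictly between the fragment's first and last residue columns
    (internal gaps belong to the domain); rows of non-member genes are all
    zero.
    """
    cells = np.zeros((alignment.n_seq, alignment.n_pos), dtype=np.uint8)
    for gene in cluster.gene_ids:
        frag = cluster.members[gene]
        row = alignment.row_index(gene)
        cols = project_fragment(alignment, row, frag.begin, frag.end)
        cells[row, cols[0] : cols[-1] + 1] = 1
    return DomainMatrix(alignment, cells)
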