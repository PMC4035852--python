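"""The five refinement operators and the pipeline driver.

The pipeline takes a domain-level ortholog clustering and applies, in fixed
order: merge, merge_divide_tree, move_boundary, create_boundary,
divide_tree. The first four maximize the DSP score; the last applies the
species-overlap rule on gene trees. Every operator works on the multiple
alignment of the full-length proteins spanning a pair of adjacent clusters
(clusters sharing a split gene), obtained from a pluggable alignment
provider; trees come from a pluggable tree provider. The built-in providers
(a deterministic progressive profile aligner and neighbor joining on
p-distances) need no external binaries; Clustal-Omega- and FastTree-style
subprocess providers are available for production use.

All iteration orders are sorted and every tie-break is deterministic, so a
rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import os
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    ALPHABET,
    AlignmentMatrix,
    Cluster,
    ClusteringState,
    Fragment,
    GAP,
    ScoreParams,
    load_score_matrix,
    validate_state,
)
from .dsp import DspEngine, normalized_change
from .trees import GeneTree, best_root_by_tdiff, min_height_root, species_overlap

logger = logging.getLogger("dsprefine")

STEP_ORDER = (
    "merge",
    "merge_divide_tree",
    "move_boundary",
    "create_boundary",
    "divide_tree",
)


class ProviderError(RuntimeError):
    """An alignment or tree provider failed for one cluster-pair context."""


# ---------------------------------------------------------------------------
# Built-in deterministic progressive aligner
# ---------------------------------------------------------------------------


def _affine_dp_kernel(S, go, ge):  # pragma: no cover - exercised via aligner
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -go - ge * i
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -go - ge * j
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = p
            a = M[i - 1, j] - go - ge
            p = 0
            b = X[i - 1, j] - ge
            if b > a:
                a = b
                p = 1
            b = Y[i - 1, j] - go - ge
            if b > a:
                a = b
                p = 2
            X[i, j] = a
            pX[i, j] = p
            a = M[i, j - 1] - go - ge
            p = 0
            b = X[i, j - 1] - go - ge
            if b > a:
                a = b
                p = 1
            b = Y[i, j - 1] - ge
            if b > a:
                a = b
                p = 2
            Y[i, j] = a
            pY[i, j] = p
    return M, X, Y, pM, pX, pY


try:  # numba accelerates the DP; the plain function is the fallback
    from numba import njit

    _affine_dp = njit(cache=False)(_affine_dp_kernel)
except Exception:  # pragma: no cover
    _affine_dp = _affine_dp_kernel


_K = len(ALPHABET)


class _Profile:
    """Rows of an alignment under construction, with column residue counts."""

    def __init__(self, ids: List[str], codes: np.ndarray) -> None:
        self.ids = ids
        self.codes = codes  # (n_rows, n_cols) int8, 0 == gap

    @classmethod
    def from_sequence(cls, gene_id: str, codes: np.ndarray) -> "_Profile":
        return cls([gene_id], codes.reshape(1, -1))

    def counts(self) -> Tuple[np.ndarray, np.ndarray]:
        n_cols = self.codes.shape[1]
        freq = np.zeros((n_cols, _K))
        cols = np.arange(n_cols)
        for row in self.codes:
            freq[cols, row] += 1.0
        freq[:, 0] = 0.0  # gaps do not score
        n_res = np.maximum(freq.sum(axis=1), 1.0)
        return freq, n_res


class BuiltinAligner:
    """Deterministic progressive aligner.

    Sequences are folded into a growing profile in descending length order
    (ties by input order): the longest proteins lay out the full domain
    architecture first, and shorter single-domain proteins then settle into
    the matching block. Profile-profile columns score as the
    residue-frequency average of the substitution matrix; gaps use the same
    G_open/G_ext model as the DSP score. Adequate for moderately diverged
    protein families; production runs can plug in an external aligner
    instead.
    """

    def __init__(self, params: Optional[ScoreParams] = None) -> None:
        self.params = params or ScoreParams()
        self.matrix = load_score_matrix(self.params.score_matrix_name)

    def align(self, items: Sequence[Tuple[str, str]]) -> AlignmentMatrix:
        from .core import encode

        if not items:
            return AlignmentMatrix([], [])
        order = sorted(
            range(len(items)), key=lambda k: (-len(items[k][1]), k)
        )
        profiles = [
            _Profile.from_sequence(items[k][0], encode(items[k][1]))
            for k in order
        ]
        current = profiles[0]
        for nxt in profiles[1:]:
            current = self._merge(current, nxt)
        # restore the caller's row order
        pos = {gid: r for r, gid in enumerate(current.ids)}
        rows = [
            "".join(ALPHABET[c] for c in current.codes[pos[gid]])
            for gid, _ in items
        ]
        return AlignmentMatrix(rows, [gid for gid, _ in items])

    def _merge(self, pa: _Profile, pb: _Profile) -> _Profile:
        fa, na = pa.counts()
        fb, nb = pb.counts()
        S = (fa @ self.matrix @ fb.T) / np.outer(na, nb)
        go, ge = self.params.gap_open, self.params.gap_ext
        M, X, Y, pM, pX, pY = _affine_dp(S, go, ge)
        n, m = S.shape
        # traceback; tie preference M > X > Y
        state = 0
        best = M[n, m]
        if X[n, m] > best:
            best, state = X[n, m], 1
        if Y[n, m] > best:
            best, state = Y[n, m], 2
        i, j = n, m
        ops: List[Tuple[bool, bool]] = []
        while i > 0 or j > 0:
            if state == 0:
                ops.append((True, True))
                state = pM[i, j]
                i, j = i - 1, j - 1
            elif state == 1:
                ops.append((True, False))
                state = pX[i, j]
                i -= 1
            else:
                ops.append((False, True))
                state = pY[i, j]
                j -= 1
        ops.reverse()
        n_cols = len(ops)
        ra, rb = pa.codes.shape[0], pb.codes.shape[0]
        out = np.zeros((ra + rb, n_cols), dtype=np.int8)
        ia = ib = 0
        for col, (ca, cb) in enumerate(ops):
            if ca:
                out[:ra, col] = pa.codes[:, ia]
                ia += 1
            if cb:
                out[ra:, col] = pb.codes[:, ib]
                ib += 1
        return _Profile(pa.ids + pb.ids, out)


class ExternalAligner:
    """Subprocess aligner following the Clustal Omega CLI contract.

    `command` is a template with ``{input}`` and ``{output}`` placeholders,
    e.g. ``clustalo -i {input} -o {output} --force`` or
    ``mafft --auto {input} > {output}`` (run through the shell).
    """

    def __init__(self, command: str) -> None:
        self.command = command

    def align(self, items: Sequence[Tuple[str, str]]) -> AlignmentMatrix:
        from . import io as dio

        if not items:
            return AlignmentMatrix([], [])
        with tempfile.TemporaryDirectory(prefix="dsprefine-aln-") as tmp:
            inp = os.path.join(tmp, "in.fasta")
            out = os.path.join(tmp, "out.fasta")
            dio.write_fasta(dict(items), inp)
            cmd = self.command.format(input=inp, output=out)
            try:
                subprocess.run(
                    cmd, shell=True, check=True, capture_output=True
                )
            except (subprocess.CalledProcessError, OSError) as exc:
                raise ProviderError(f"external aligner failed: {exc}") from exc
            aln = dio.read_aligned_fasta(out)
        order = {gid: k for k, (gid, _) in enumerate(items)}
        missing = set(order) - set(aln.row_ids)
        if missing:
            raise ProviderError(
                f"external aligner dropped sequences: {sorted(missing)}"
            )
        idx = sorted(range(aln.n_seq), key=lambda r: order[aln.row_ids[r]])
        return AlignmentMatrix(
            [aln.rows[r] for r in idx], [aln.row_ids[r] for r in idx]
        )


# ---------------------------------------------------------------------------
# Built-in / external tree builders
# ---------------------------------------------------------------------------


class BuiltinTreeBuilder:
    """Neighbor joining on p-distances of the alignment."""

    def build(self, alignment: AlignmentMatrix) -> GeneTree:
        from skbio import DistanceMatrix
        from skbio.tree import nj

        n = alignment.n_seq
        if n < 2:
            raise ProviderError("tree needs at least 2 sequences")
        res = alignment.residue_mask
        codes = alignment.codes
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                shared = res[i] & res[j]
                total = int(shared.sum())
                if total == 0:
                    d = 1.0
                else:
                    d = float((codes[i][shared] != codes[j][shared]).mean())
                dist[i, j] = dist[j, i] = d
        if n == 2:
            tree = GeneTree()
            a = tree.add_leaf(alignment.row_ids[0])
            b = tree.add_leaf(alignment.row_ids[1])
            tree.add_edge(a, b, dist[0, 1])
            return tree
        dm = DistanceMatrix(dist, ids=list(alignment.row_ids))
        return GeneTree.from_skbio(nj(dm))


class ExternalTreeBuilder:
    """Subprocess tree builder following the FastTree CLI contract.

    `command` takes ``{input}`` (aligned FASTA) and optionally ``{output}``;
    without ``{output}`` the Newick tree is read from stdout.
    """

    def __init__(self, command: str) -> None:
        self.command = command

    def build(self, alignment: AlignmentMatrix) -> GeneTree:
        from . import io as dio

        with tempfile.TemporaryDirectory(prefix="dsprefine-tree-") as tmp:
            inp = os.path.join(tmp, "in.afa")
            dio.write_aligned_fasta(alignment, inp)
            if "{output}" in self.command:
                out = os.path.join(tmp, "out.nwk")
                cmd = self.command.format(input=inp, output=out)
            else:
                out = None
                cmd = self.command.format(input=inp)
            try:
                proc = subprocess.run(
                    cmd, shell=True, check=True, capture_output=True, text=True
                )
            except (subprocess.CalledProcessError, OSError) as exc:
                raise ProviderError(f"external tree builder failed: {exc}")
            if out is None:
                return dio.parse_newick(proc.stdout)
            return dio.read_newick(out)


# ---------------------------------------------------------------------------
# Providers with content-hash caching
# ---------------------------------------------------------------------------


def _content_key(items: Sequence[Tuple[str, str]]) -> str:
    h = hashlib.sha1()
    for gid, seq in items:
        h.update(gid.encode())
        h.update(b"\0")
        h.update(seq.encode())
        h.update(b"\n")
    return h.hexdigest()


class AlignmentProvider:
    """Supplies per-context multiple alignments, cached by content hash."""

    def __init__(
        self,
        sequences: Mapping[str, str],
        aligner=None,
        params: Optional[ScoreParams] = None,
        cache_dir: Optional[str] = None,
    ) -> None:
        self.sequences = dict(sequences)
        self.aligner = aligner or BuiltinAligner(params)
        self.cache_dir = cache_dir
        self._memory: Dict[str, AlignmentMatrix] = {}
        if cache_dir:
            os.makedirs(cache_dir, exist_ok=True)

    def _aligned(self, items: List[Tuple[str, str]]) -> AlignmentMatrix:
        from . import io as dio

        key = _content_key(items)
        if key in self._memory:
            return self._memory[key]
        path = (
            os.path.join(self.cache_dir, key + ".afa")
            if self.cache_dir
            else None
        )
        if path and os.path.exists(path):
            aln = dio.read_aligned_fasta(path)
        else:
            try:
                aln = self.aligner.align(items)
            except ProviderError:
                raise
            except Exception as exc:
                raise ProviderError(f"aligner failed: {exc}") from exc
            if path:
                dio.write_aligned_fasta(aln, path)
        self._memory[key] = aln
        return aln

    def full_length(self, gene_ids: Iterable[str]) -> AlignmentMatrix:
        """Alignment of the full-length proteins of `gene_ids` (sorted)."""
        genes = sorted(set(gene_ids))
        missing = [g for g in genes if g not in self.sequences]
        if missing:
            raise ProviderError(f"no sequence for genes {missing}")
        return self._aligned([(g, self.sequences[g]) for g in genes])

    def fragments(self, frags: Iterable[Fragment]) -> AlignmentMatrix:
        """Alignment of fragment subsequences, rows keyed by gene id."""
        items = []
        for f in sorted(frags, key=lambda f: f.gene_id):
            if f.gene_id not in self.sequences:
                raise ProviderError(f"no sequence for gene {f.gene_id}")
            items.append((f.gene_id, self.sequences[f.gene_id][f.begin : f.end]))
        return self._aligned(items)


class TreeProvider:
    """Supplies gene trees for alignments, cached by alignment content."""

    def __init__(self, builder=None, cache_dir: Optional[str] = None) -> None:
        self.builder = builder or BuiltinTreeBuilder()
        self.cache_dir = cache_dir
        self._memory: Dict[str, GeneTree] = {}
        if cache_dir:
            os.makedirs(cache_dir, exist_ok=True)

    def tree_for(self, alignment: AlignmentMatrix) -> GeneTree:
        from . import io as dio

        key = _content_key(list(zip(alignment.row_ids, alignment.rows)))
        if key in self._memory:
            return self._memory[key]
        path = (
            os.path.join(self.cache_dir, key + ".nwk")
            if self.cache_dir
            else None
        )
        if path and os.path.exists(path):
            tree = dio.read_newick(path)
        else:
            try:
                tree = self.builder.build(alignment)
            except ProviderError:
                raise
            except Exception as exc:
                raise ProviderError(f"tree builder failed: {exc}") from exc
            if path:
                dio.write_newick(tree, path)
        self._memory[key] = tree
        return tree


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------


@dataclass
class AdjacentPair:
    """Two clusters sharing at least one gene with abutting fragments."""

    cluster_a: str  # lexicographically smaller id
    cluster_b: str
    shared_genes: List[str]
    #: gene -> True iff cluster_a holds the N-terminal fragment of the gene
    a_is_nterm: Dict[str, bool] = field(default_factory=dict)


def find_adjacent_pairs(state: ClusteringState) -> List[AdjacentPair]:
    """All unordered cluster pairs linked by >= 1 split gene, sorted by ids.

    Only consecutive fragments of a gene (end of one == begin of the next)
    make two clusters adjacent.
    """
    found: Dict[Tuple[str, str], AdjacentPair] = {}
    for gene, entries in sorted(state.gene_index().items()):
        for (cid1, f1), (cid2, f2) in zip(entries, entries[1:]):
            if f1.end != f2.begin or cid1 == cid2:
                continue
            a, b = sorted((cid1, cid2))
            pair = found.setdefault(
                (a, b), AdjacentPair(a, b, [], {})
            )
            if gene not in pair.a_is_nterm:
                pair.shared_genes.append(gene)
                pair.a_is_nterm[gene] = cid1 == a
    return [found[key] for key in sorted(found)]


# ---------------------------------------------------------------------------
# Step machinery
# ---------------------------------------------------------------------------


@dataclass
class StepReport:
    step_name: str
    n_examined: int
    n_applied: int
    score_changes: List[float]
    state_after: ClusteringState


def _indicator(
    aln: AlignmentMatrix, frags: Iterable[Fragment]
) -> np.ndarray:
    from .core import indicator_for_fragments

    return indicator_for_fragments(aln, frags)


def _coalesce_gene_fragments(gene: str, frags: List[Fragment]) -> Fragment:
    frags = sorted(frags)
    begin, end = frags[0].begin, frags[0].end
    for f in frags[1:]:
        if f.begin > end:
            logger.warning(
                "merging non-adjacent fragments of %s across a %d-residue gap",
                gene,
                f.begin - end,
            )
        end = max(end, f.end)
    return Fragment(gene, begin, end)


def _merged_members(state: ClusteringState, cluster_ids: Iterable[str]) -> List[Fragment]:
    per_gene: Dict[str, List[Fragment]] = {}
    for cid in cluster_ids:
        for frag in state.clusters[cid].members.values():
            per_gene.setdefault(frag.gene_id, []).append(frag)
    return [
        _coalesce_gene_fragments(g, fl) for g, fl in sorted(per_gene.items())
    ]


def _fresh_id(state: ClusteringState, base: str) -> str:
    k = 2
    while f"{base}/{k}" in state.clusters:
        k += 1
    return f"{base}/{k}"


def _pair_context(
    state: ClusteringState,
    pair: AdjacentPair,
    provider: AlignmentProvider,
    params: ScoreParams,
):
    genes = sorted(
        set(state.clusters[pair.cluster_a].members)
        | set(state.clusters[pair.cluster_b].members)
    )
    aln = provider.full_length(genes)
    return aln, DspEngine(aln, params)


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------


def merge_step(
    state: ClusteringState,
    provider: AlignmentProvider,
    params: Optional[ScoreParams] = None,
) -> StepReport:
    """Merge adjacent cluster pairs whose normalized score change exceeds
    the merge threshold; all marked pairs are merged at once (transitive
    closure via union-find).
    """
    params = params or ScoreParams()
    pairs = find_adjacent_pairs(state)
    marked: List[Tuple[str, str]] = []
    changes: List[float] = []
    n_examined = 0
    for pair in pairs:
        n_examined += 1
        try:
            aln, engine = _pair_context(state, pair, provider, params)
        except ProviderError as exc:
            logger.warning(
                "merge: skipping pair (%s, %s): %s",
                pair.cluster_a,
                pair.cluster_b,
                exc,
            )
            continue
        ca = state.clusters[pair.cluster_a]
        cb = state.clusters[pair.cluster_b]
        s_before = engine.score_indicator(
            _indicator(aln, ca.members.values())
        ) + engine.score_indicator(_indicator(aln, cb.members.values()))
        merged = _merged_members(state, (pair.cluster_a, pair.cluster_b))
        s_after = engine.score_indicator(_indicator(aln, merged))
        delta = normalized_change(s_before, s_after, aln)
        changes.append(delta)
        if delta > params.merge_threshold:
            marked.append((pair.cluster_a, pair.cluster_b))

    # union-find over marked pairs
    parent: Dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in marked:
        ra, rb = find(a), find(b)
        if ra != rb:
            lo, hi = sorted((ra, rb))
            parent[hi] = lo

    groups: Dict[str, List[str]] = {}
    for cid in list(parent):
        groups.setdefault(find(cid), []).append(cid)

    new_state = state.copy()
    for root, members in sorted(groups.items()):
        if len(members) < 2:
            continue
        frags = _merged_members(new_state, members)
        for cid in members:
            new_state.remove_cluster(cid)
        cluster = Cluster(min(members))
        for frag in frags:
            cluster.add(frag)
        new_state.add_cluster(cluster)
    return StepReport("merge", n_examined, len(marked), changes, new_state)


# ---------------------------------------------------------------------------
# merge_divide_tree
# ---------------------------------------------------------------------------


def merge_divide_tree_step(
    state: ClusteringState,
    provider: AlignmentProvider,
    tree_provider: TreeProvider,
    params: Optional[ScoreParams] = None,
) -> StepReport:
    """Temporarily merge each adjacent pair and re-divide it as the best
    t_diff split of the gene tree into two full-length groups; keep the
    re-grouping only when the DSP score increases.
    """
    params = params or ScoreParams()
    new_state = state.copy()
    changes: List[float] = []
    n_examined = n_applied = 0
    touched: set = set()
    for pair in find_adjacent_pairs(state):
        if pair.cluster_a in touched or pair.cluster_b in touched:
            continue
        ca = new_state.clusters[pair.cluster_a]
        cb = new_state.clusters[pair.cluster_b]
        genes = sorted(set(ca.members) | set(cb.members))
        if len(genes) < 3:
            continue
        n_examined += 1
        try:
            aln, engine = _pair_context(new_state, pair, provider, params)
            tree = tree_provider.tree_for(aln)
        except ProviderError as exc:
            logger.warning(
                "merge_divide_tree: skipping pair (%s, %s): %s",
                pair.cluster_a,
                pair.cluster_b,
                exc,
            )
            continue
        if len(tree.leaves) < 3:
            continue
        shared = set(ca.members) & set(cb.members)
        g1 = set(ca.members) - shared
        g2 = set(cb.members) - shared
        rooting = best_root_by_tdiff(tree, g1, g2, shared)
        t1, t2 = rooting.subtrees
        if not t1 or not t2:
            continue
        spans = {
            f.gene_id: f
            for f in _merged_members(
                new_state, (pair.cluster_a, pair.cluster_b)
            )
        }
        x1 = _indicator(aln, (spans[g] for g in sorted(t1)))
        x2 = _indicator(aln, (spans[g] for g in sorted(t2)))
        s_new = engine.score_indicator(x1) + engine.score_indicator(x2)
        s_old = engine.score_indicator(
            _indicator(aln, ca.members.values())
        ) + engine.score_indicator(_indicator(aln, cb.members.values()))
        delta = normalized_change(s_old, s_new, aln)
        changes.append(delta)
        if s_new > s_old:
            base = min(pair.cluster_a, pair.cluster_b)
            new_state.remove_cluster(pair.cluster_a)
            new_state.remove_cluster(pair.cluster_b)
            c1 = Cluster(base)
            for g in sorted(t1):
                c1.add(spans[g])
            new_state.add_cluster(c1)
            c2 = Cluster(_fresh_id(new_state, base))
            for g in sorted(t2):
                c2.add(spans[g])
            new_state.add_cluster(c2)
            touched.update({pair.cluster_a, pair.cluster_b})
            n_applied += 1
    return StepReport(
        "merge_divide_tree", n_examined, n_applied, changes, new_state
    )


# ---------------------------------------------------------------------------
# move_boundary
# ---------------------------------------------------------------------------


@dataclass
class _SharedGene:
    gene: str
    row: int
    region_begin: int  # residue coords on the gene
    region_end: int
    region_cols: np.ndarray  # alignment columns of the region's residues
    a_is_nterm: bool


def _shared_gene_info(
    state: ClusteringState, pair: AdjacentPair, aln: AlignmentMatrix
) -> List[_SharedGene]:
    ca = state.clusters[pair.cluster_a]
    cb = state.clusters[pair.cluster_b]
    out = []
    for gene in pair.shared_genes:
        fa, fb = ca.members[gene], cb.members[gene]
        begin = min(fa.begin, fb.begin)
        end = max(fa.end, fb.end)
        row = aln.row_index(gene)
        cols = aln.residue_columns(row)[begin:end]
        out.append(
            _SharedGene(gene, row, begin, end, cols, pair.a_is_nterm[gene])
        )
    return out


def move_boundary_step(
    state: ClusteringState,
    provider: AlignmentProvider,
    params: Optional[ScoreParams] = None,
) -> StepReport:
    """Move all split boundaries of each adjacent pair to one shared
    alignment column, chosen by exhaustive N-to-C scan of the DSP score;
    the move is kept only on strict improvement.
    """
    params = params or ScoreParams()
    new_state = state.copy()
    changes: List[float] = []
    n_examined = n_applied = 0
    for pair in find_adjacent_pairs(state):
        if (
            pair.cluster_a not in new_state.clusters
            or pair.cluster_b not in new_state.clusters
        ):
            continue
        n_examined += 1
        try:
            aln, engine = _pair_context(new_state, pair, provider, params)
        except ProviderError as exc:
            logger.warning(
                "move_boundary: skipping pair (%s, %s): %s",
                pair.cluster_a,
                pair.cluster_b,
                exc,
            )
            continue
        ca = new_state.clusters[pair.cluster_a]
        cb = new_state.clusters[pair.cluster_b]
        shared = _shared_gene_info(new_state, pair, aln)
        shared_names = {s.gene for s in shared}
        base_a = _indicator(
            aln,
            (f for g, f in ca.members.items() if g not in shared_names),
        )
        base_b = _indicator(
            aln,
            (f for g, f in cb.members.items() if g not in shared_names),
        )
        s0 = engine.score_indicator(
            _indicator(aln, ca.members.values())
        ) + engine.score_indicator(_indicator(aln, cb.members.values()))

        candidates = np.unique(np.concatenate([s.region_cols for s in shared]))
        best_score, best_col = -np.inf, None
        for c in candidates:
            xa = base_a.copy()
            xb = base_b.copy()
            ok = True
            for s in shared:
                left = s.region_cols[s.region_cols < c]
                right = s.region_cols[s.region_cols >= c]
                if left.size == 0 or right.size == 0:
                    ok = False
                    break
                xn, xc = (xa, xb) if s.a_is_nterm else (xb, xa)
                xn[s.row, left] = True
                xc[s.row, right] = True
            if not ok:
                continue
            score = engine.score_indicator(xa) + engine.score_indicator(xb)
            if score > best_score + 1e-12:
                best_score, best_col = score, int(c)
        if best_col is not None and best_score > s0 + 1e-9:
            for s in shared:
                k = int((s.region_cols < best_col).sum())
                boundary = s.region_begin + k
                left = Fragment(s.gene, s.region_begin, boundary)
                right = Fragment(s.gene, boundary, s.region_end)
                if s.a_is_nterm:
                    ca.members[s.gene] = left
                    cb.members[s.gene] = right
                else:
                    cb.members[s.gene] = left
                    ca.members[s.gene] = right
            n_applied += 1
            changes.append(normalized_change(s0, best_score, aln))
        else:
            changes.append(0.0)
    return StepReport(
        "move_boundary", n_examined, n_applied, changes, new_state
    )


# ---------------------------------------------------------------------------
# create_boundary
# ---------------------------------------------------------------------------


def create_boundary_step(
    state: ClusteringState,
    provider: AlignmentProvider,
    params: Optional[ScoreParams] = None,
) -> StepReport:
    """Split, at the consensus boundary column of each adjacent pair, the
    member genes that are not yet split; the whole proposed set is accepted
    iff it increases the DSP score.
    """
    params = params or ScoreParams()
    new_state = state.copy()
    changes: List[float] = []
    n_examined = n_applied = 0
    for pair in find_adjacent_pairs(state):
        if (
            pair.cluster_a not in new_state.clusters
            or pair.cluster_b not in new_state.clusters
        ):
            continue
        n_examined += 1
        try:
            aln, engine = _pair_context(new_state, pair, provider, params)
        except ProviderError as exc:
            logger.warning(
                "create_boundary: skipping pair (%s, %s): %s",
                pair.cluster_a,
                pair.cluster_b,
                exc,
            )
            continue
        ca = new_state.clusters[pair.cluster_a]
        cb = new_state.clusters[pair.cluster_b]
        shared = _shared_gene_info(new_state, pair, aln)
        if not shared:
            changes.append(0.0)
            continue
        # consensus column: modal boundary column among split members
        boundary_cols = []
        for s in shared:
            fa = ca.members[s.gene] if s.a_is_nterm else cb.members[s.gene]
            k = fa.end - s.region_begin  # residues on the N side
            boundary_cols.append(int(s.region_cols[k]))
        counts = Counter(boundary_cols)
        consensus = min(
            counts, key=lambda col: (-counts[col], col)
        )
        a_is_nterm = (
            sum(1 for s in shared if s.a_is_nterm) * 2 >= len(shared)
        )
        nterm, cterm = (
            (ca, cb) if a_is_nterm else (cb, ca)
        )
        # candidates: genes in exactly one of the two clusters, spanning the
        # consensus column
        proposals = []
        for gene in sorted(set(ca.members) ^ set(cb.members)):
            holder = ca if gene in ca.members else cb
            frag = holder.members[gene]
            row = aln.row_index(gene)
            cols = aln.residue_columns(row)[frag.begin : frag.end]
            left = cols[cols < consensus]
            right = cols[cols >= consensus]
            if left.size == 0 or right.size == 0:
                continue  # would create an empty domain
            proposals.append((gene, holder, frag, int(left.size)))
        if not proposals:
            changes.append(0.0)
            continue
        s_old = engine.score_indicator(
            _indicator(aln, ca.members.values())
        ) + engine.score_indicator(_indicator(aln, cb.members.values()))
        trial_n = dict(nterm.members)
        trial_c = dict(cterm.members)
        for gene, holder, frag, k in proposals:
            boundary = frag.begin + k
            trial_n.pop(gene, None)
            trial_c.pop(gene, None)
            trial_n[gene] = Fragment(gene, frag.begin, boundary)
            trial_c[gene] = Fragment(gene, boundary, frag.end)
        s_new = engine.score_indicator(
            _indicator(aln, trial_n.values())
        ) + engine.score_indicator(_indicator(aln, trial_c.values()))
        changes.append(normalized_change(s_old, s_new, aln))
        if s_new > s_old:
            nterm.members.clear()
            nterm.members.update(trial_n)
            cterm.members.clear()
            cterm.members.update(trial_c)
            n_applied += 1
    return StepReport(
        "create_boundary", n_examined, n_applied, changes, new_state
    )


# ---------------------------------------------------------------------------
# divide_tree
# ---------------------------------------------------------------------------


def divide_tree_step(
    state: ClusteringState,
    provider: AlignmentProvider,
    tree_provider: TreeProvider,
    params: Optional[ScoreParams] = None,
) -> StepReport:
    """Divide clusters whose min-height-rooted gene tree shows a species
    overlap >= R_sp between the two root subtrees; applied recursively to
    the resulting subgroups.
    """
    params = params or ScoreParams()
    new_state = state.copy()
    changes: List[float] = []
    n_examined = n_applied = 0
    queue = list(new_state.cluster_ids())
    while queue:
        cid = queue.pop(0)
        cluster = new_state.clusters[cid]
        if len(cluster) < 4:
            continue
        n_examined += 1
        try:
            aln = provider.fragments(cluster.members.values())
            tree = tree_provider.tree_for(aln)
        except ProviderError as exc:
            logger.warning("divide_tree: skipping cluster %s: %s", cid, exc)
            continue
        if len(tree.leaves) < 3:
            continue
        rooting = min_height_root(tree)
        t1, t2 = rooting.subtrees
        if not t1 or not t2:
            continue
        overlap = species_overlap(t1, t2)
        if overlap >= params.species_overlap_threshold:
            members = dict(cluster.members)
            new_state.remove_cluster(cid)
            c1 = Cluster(cid)
            for g in sorted(t1):
                c1.add(members[g])
            new_state.add_cluster(c1)
            cid2 = _fresh_id(new_state, cid)
            c2 = Cluster(cid2)
            for g in sorted(t2):
                c2.add(members[g])
            new_state.add_cluster(c2)
            queue.extend([cid, cid2])
            n_applied += 1
            changes.append(overlap)
    return StepReport(
        "divide_tree", n_examined, n_applied, changes, new_state
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    state: ClusteringState,
    provider: AlignmentProvider,
    tree_provider: Optional[TreeProvider] = None,
    params: Optional[ScoreParams] = None,
    steps: Optional[Sequence[str]] = None,
    checkpoint_path: Optional[str] = None,
) -> List[StepReport]:
    """Apply the refinement steps in the fixed pipeline order.

    `steps` may restrict the run to an ordered subset of STEP_ORDER. On an
    unexpected failure the last valid state is written to
    `checkpoint_path` (if given) before the exception propagates.
    """
    params = params or ScoreParams()
    tree_provider = tree_provider or TreeProvider()
    steps = list(steps) if steps is not None else list(STEP_ORDER)
    unknown = set(steps) - set(STEP_ORDER)
    if unknown:
        raise ValueError(f"unknown steps: {sorted(unknown)}")
    problems = validate_state(state, provider.sequences)
    if problems:
        raise ValueError("invalid input state: " + "; ".join(problems))
    reports: List[StepReport] = []
    current = state
    for step in steps:
        try:
            if step == "merge":
                report = merge_step(current, provider, params)
            elif step == "merge_divide_tree":
                report = merge_divide_tree_step(
                    current, provider, tree_provider, params
                )
            elif step == "move_boundary":
                report = move_boundary_step(current, provider, params)
            elif step == "create_boundary":
                report = create_boundary_step(current, provider, params)
            else:
                report = divide_tree_step(
                    current, provider, tree_provider, params
                )
        except Exception:
            if checkpoint_path:
                from . import io as dio

                dio.write_clusters(current, checkpoint_path)
                logger.error(
                    "step %s failed; last valid state saved to %s",
                    step,
                    checkpoint_path,
                )
            raise
        problems = validate_state(report.state_after, provider.sequences)
        if problems:
            raise AssertionError(
                f"step {step} produced an invalid state: "
                + "; ".join(problems)
            )
        logger.info(
            "%s: examined %d, applied %d",
            step,
            report.n_examined,
            report.n_applied,
        )
        reports.append(report)
        current = report.state_after
    return reports
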