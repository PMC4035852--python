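"""The domain-specific sum-of-pairs (DSP) score.

The DSP score S(A, D) of a domain D on a multiple alignment A is a
sum-of-pairs alignment score restricted to the cells of the domain, with
inconsistencies in domain boundary positions charged as open gaps:

    S(A, D) = sum_{i < i'} [ sum_j s_dom(a_ij, a_i'j, d_ij, d_i'j)
                             - n_Gopen(a_i., a_i'., d_i., d_i'.) * G_open ]

where s_dom returns the substitution-matrix score when both cells hold
in-domain residues, -G_ext when exactly one does, and 0 when neither does,
and n_Gopen counts maximal runs of columns in which exactly one of the two
rows presents an in-domain residue (so every mismatch of domain start or
end columns between two rows opens a gap).

Semantics fixed here:

* the pair sum runs over rows that carry at least one in-domain residue;
  a row entirely outside the domain contributes 0 to every pair it appears
  in (its cluster simply does not contain that gene);
* columns where both rows are gaps are transparent: they neither score nor
  interrupt a gap run (standard pairwise-projection practice, and required
  for the score to be invariant under all-gap column insertion);
* G_ext enters with a negative sign: gaps are penalties.

Scores are normalized by N_seq * N_aa of the alignment context so that
score changes are comparable across cluster pairs of different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .core import (
    AlignmentMatrix,
    DomainMatrix,
    ScoreParams,
    encode,
    is_residue,
    load_score_matrix,
)

__all__ = [
    "DspResult",
    "DspEngine",
    "s_dom",
    "count_open_gaps",
    "dsp_score",
    "normalized_change",
]


@dataclass
class DspResult:
    """Raw DSP score with its per-pair decomposition."""

    raw_score: float
    pair_terms: Dict[Tuple[int, int], float]
    open_gap_count_total: int

    def __float__(self) -> float:
        return self.raw_score


def s_dom(
    a: str, a_prime: str, d: int, d_prime: int, params: ScoreParams
) -> float:
    """Score one pair of alignment cells under the domain-aware scheme."""
    matrix = _matrix_cache(params.score_matrix_name)
    x = 1 if (is_residue(a) and d) else 0
    y = 1 if (is_residue(a_prime) and d_prime) else 0
    if x and y:
        return float(matrix[encode(a)[0], encode(a_prime)[0]])
    if x or y:
        return -params.gap_ext
    return 0.0


def count_open_gaps(row_i, row_i_prime, dom_i, dom_i_prime) -> int:
    """n_Gopen for one row pair.

    `row_i`/`row_i_prime` are equal-length aligned strings, `dom_i`/
    `dom_i_prime` 0/1 indicator sequences of the same length. Counts maximal
    runs of columns where exactly one row presents an in-domain residue;
    both-gap columns are transparent.
    """
    if not (len(row_i) == len(row_i_prime) == len(dom_i) == len(dom_i_prime)):
        raise ValueError("rows and domain rows must have equal length")
    runs = 0
    prev = 0  # in-run state at the last non-transparent column
    for a, ap, d, dp in zip(row_i, row_i_prime, dom_i, dom_i_prime):
        ra, rb = is_residue(a), is_residue(ap)
        if not ra and not rb:
            continue  # transparent
        x = 1 if (ra and int(d)) else 0
        y = 1 if (rb and int(dp)) else 0
        z = x ^ y
        if z and not prev:
            runs += 1
        prev = z
    return runs


_MATRICES: Dict[str, np.ndarray] = {}


def _matrix_cache(name: str) -> np.ndarray:
    if name not in _MATRICES:
        _MATRICES[name] = load_score_matrix(name)
    return _MATRICES[name]


class DspEngine:
    """Vectorized DSP evaluation for one alignment context.

    Caches the per-column substitution scores of every row pair so that
    repeated evaluations with different domain indicators (the inner loop of
    boundary optimization) cost only boolean work.
    """

    def __init__(self, alignment: AlignmentMatrix, params: ScoreParams) -> None:
        self.alignment = alignment
        self.params = params
        self.matrix = _matrix_cache(params.score_matrix_name)
        n = alignment.n_seq
        iu, ju = np.triu_indices(n, k=1)
        self._iu, self._ju = iu, ju
        self._pair_pos = {
            (int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))
        }
        codes = alignment.codes
        # (n_pairs, n_pos) substitution scores; ~n^2*L/2 doubles, desk scale
        self._pairscore = self.matrix[codes[iu], codes[ju]]
        res = alignment.residue_mask
        self._transparent = ~(res[iu] | res[ju])
        self._prev_lookup = self._build_prev_lookup()

    def _build_prev_lookup(self) -> np.ndarray:
        """Index of the previous non-transparent column, -1 if none."""
        n_pairs, n_pos = self._transparent.shape
        if n_pos == 0:
            return np.zeros((n_pairs, 0), dtype=np.int64)
        idx = np.where(~self._transparent, np.arange(n_pos)[None, :], -1)
        last = np.maximum.accumulate(idx, axis=1)
        prev = np.concatenate(
            [np.full((n_pairs, 1), -1, dtype=np.int64), last[:, :-1]], axis=1
        )
        return prev

    def score_indicator(
        self, x: np.ndarray, detail: bool = False
    ) -> "float | DspResult":
        """DSP score of the domain whose in-domain-residue mask is `x`.

        `x[i, j]` is True iff cell (i, j) is a residue belonging to the
        domain (b(a_ij) * d_ij == 1).
        """
        members = np.flatnonzero(x.any(axis=1))
        if members.size < 2:
            return DspResult(0.0, {}, 0) if detail else 0.0
        pos = np.array(
            [
                self._pair_pos[(int(i), int(j))]
                for k, i in enumerate(members)
                for j in members[k + 1 :]
            ],
            dtype=np.int64,
        )
        ii = self._iu[pos]
        jj = self._ju[pos]
        xi = x[ii]
        xj = x[jj]
        both = xi & xj
        sub = np.where(both, self._pairscore[pos], 0.0).sum(axis=1)
        z = xi ^ xj
        ext = z.sum(axis=1) * self.params.gap_ext
        prev = self._prev_lookup[pos]
        prev_z = np.take_along_axis(z, np.maximum(prev, 0), axis=1)
        prev_z &= prev >= 0
        runs = (z & ~prev_z).sum(axis=1)
        terms = sub - ext - runs * self.params.gap_open
        total = float(terms.sum())
        if not detail:
            return total
        pair_terms = {
            (int(i), int(j)): float(t) for i, j, t in zip(ii, jj, terms)
        }
        return DspResult(total, pair_terms, int(runs.sum()))


def dsp_score(
    alignment: AlignmentMatrix,
    domain: DomainMatrix,
    params: ScoreParams,
    engine: Optional[DspEngine] = None,
) -> DspResult:
    """S(A, D) with per-pair decomposition.

    Raises ValueError if the domain matrix was built for a different
    alignment shape.
    """
    if domain.cells.shape != (alignment.n_seq, alignment.n_pos):
        raise ValueError("alignment and domain matrix shapes differ")
    if engine is None:
        engine = DspEngine(alignment, params)
    x = domain.cells.astype(bool) & alignment.residue_mask
    return engine.score_indicator(x, detail=True)


def normalized_change(
    score_before: float, score_after: float, alignment: AlignmentMatrix
) -> float:
    """(S' - S) / (N_seq * N_aa) on the shared alignment context."""
    if alignment.n_seq == 0 or alignment.n_aa == 0:
        raise ValueError("cannot normalize on an empty alignment")
    return (score_after - score_before) / (alignment.n_seq * alignment.n_aa)
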