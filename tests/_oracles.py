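"""Independent brute-force oracles used by the unit and acceptance tests.

Written directly from the score definition as plain triple loops over
rows, row pairs and columns — deliberately sharing no code with the
vectorized implementation they check.
"""

from typing import Dict, List, Sequence, Tuple

import numpy as np


def sp_pair_score(
    row_a: str,
    row_b: str,
    dom_a: Sequence[int],
    dom_b: Sequence[int],
    matrix: Dict[Tuple[str, str], float],
    gap_open: float,
    gap_ext: float,
) -> float:
    """Score one row pair: column terms minus open-gap charges."""
    total = 0.0
    runs = 0
    prev_mismatch = False
    for a, b, da, db in zip(row_a, row_b, dom_a, dom_b):
        res_a, res_b = a != "-", b != "-"
        if not res_a and not res_b:
            continue  # both gaps: transparent
        x = res_a and bool(da)
        y = res_b and bool(db)
        if x and y:
            total += matrix.get((a, b), 0.0)
            prev_mismatch = False
        elif x or y:
            total -= gap_ext
            if not prev_mismatch:
                runs += 1
            prev_mismatch = True
        else:
            prev_mismatch = False
    return total - runs * gap_open


def dsp_oracle(
    rows: List[str],
    domains: List[Sequence[int]],
    matrix: Dict[Tuple[str, str], float],
    gap_open: float,
    gap_ext: float,
) -> float:
    """Brute-force S(A, D): sum over pairs of rows with in-domain residues."""
    members = [
        i
        for i, (row, dom) in enumerate(zip(rows, domains))
        if any(c != "-" and d for c, d in zip(row, dom))
    ]
    total = 0.0
    for ai in range(len(members)):
        for bi in range(ai + 1, len(members)):
            i, j = members[ai], members[bi]
            total += sp_pair_score(
                rows[i], rows[j], domains[i], domains[j],
                matrix, gap_open, gap_ext,
            )
    return total


def matrix_as_dict(table: np.ndarray, alphabet: str) -> Dict[Tuple[str, str], float]:
    return {
        (a, b): float(table[i, j])
        for i, a in enumerate(alphabet)
        for j, b in enumerate(alphabet)
    }


def random_dsp_instance(rng: np.random.Generator, max_rows=6, max_cols=30):
    """A random gapped alignment with one random contiguous domain per row.

    Returns (rows, domain_rows); the domain of each row covers a random
    residue interval plus the gap columns spanned by it.
    """
    n = int(rng.integers(2, max_rows + 1))
    m = int(rng.integers(4, max_cols + 1))
    residues = "ACDEFGHIKLMNPQRSTVWY"
    rows = []
    for _ in range(n):
        chars = [
            "-" if rng.random() < 0.25 else residues[int(rng.integers(20))]
            for _ in range(m)
        ]
        if all(c == "-" for c in chars):
            chars[int(rng.integers(m))] = "A"
        rows.append("".join(chars))
    domains = []
    for row in rows:
        res_cols = [k for k, c in enumerate(row) if c != "-"]
        dom = [0] * m
        if rng.random() < 0.15:
            domains.append(dom)  # row entirely outside the domain
            continue
        lo = int(rng.integers(0, len(res_cols)))
        hi = int(rng.integers(lo, len(res_cols)))
        first, last = res_cols[lo], res_cols[hi]
        for k in range(first, last + 1):
            dom[k] = 1
        domains.append(dom)
    return rows, domains


def random_gene_tree(rng: np.random.Generator, n_leaves: int, species_pool=None):
    """A random weighted binary tree as (GeneTree, None); leaves named
    ``<species>:g<k>`` over a small species pool."""
    from dsprefine.trees import GeneTree

    if species_pool is None:
        species_pool = [f"s{i}" for i in range(1, 5)]
    tree = GeneTree()
    nodes = []
    for k in range(n_leaves):
        sp = species_pool[int(rng.integers(len(species_pool)))]
        nodes.append(tree.add_leaf(f"{sp}:g{k}"))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[int(i)], nodes[int(j)]
        parent = tree.new_internal()
        tree.add_edge(parent, a, float(rng.uniform(0.0, 2.0)))
        tree.add_edge(parent, b, float(rng.uniform(0.0, 2.0)))
        nodes = [n for n in nodes if n not in (a, b)] + [parent]
    tree.add_edge(nodes[0], nodes[1], float(rng.uniform(0.0, 2.0)))
    return tree
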