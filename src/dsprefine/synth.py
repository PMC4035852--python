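"""Synthetic protein families with planted domain architectures.

The generator builds a benchmark on which every pipeline operator has known
targets, with no external data:

* *single-domain families*: one ancestral domain, one ortholog per species
  — targets for the merge step once the corrupter falsely splits them;
* *two-domain families*: ancestral domains A and B; a fixed fraction of the
  species carry the fused A+B architecture (one protein split into two
  domains), the rest carry separate A and B proteins — targets for boundary
  moves (after jitter) and boundary creation (after un-splitting);
* *paralog families*: single-domain families in which a fixed fraction of
  the species also carry an in-species duplicate descending from one
  duplication event before speciation — targets for tree-based division
  once the corrupter pools the duplicates into the ortholog cluster.

Evolution is a star phylogeny per family: every gene derives from the
family consensus by i.i.d. point substitutions and indels (geometric
lengths, mean 2). This produces the alignment features the operators act on
(diverged but alignable domains, shifted boundaries, a deep split between
duplication products) without attempting realistic protein evolution.

Everything is driven by one numpy Generator; a fixed seed reproduces the
dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import Cluster, ClusteringState, Fragment

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "CorruptionResult",
    "SyntheticDataset",
    "generate_family",
    "corrupt_clustering",
    "generate_dataset",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: deterministic family-type cycle: per 5 families, 2 single-domain,
#: 2 two-domain, 1 paralog
_TYPE_CYCLE = ("single", "fused", "single", "fused", "paralog")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Rates are per site; fractions are deterministic (rounded counts of
    species), so the planted structure is stable across seeds.
    """

    n_species: int = 10
    n_families: int = 20
    domain_length_range: Tuple[int, int] = (60, 120)
    #: fraction of species carrying the fused A+B architecture in
    #: two-domain families
    fusion_fraction: float = 0.5
    #: expected substitutions per site from the family consensus
    substitution_rate: float = 0.1
    #: expected indel events per site (geometric lengths, mean 2)
    indel_rate: float = 0.01
    #: extra substitution rate on the duplication branch of paralog families
    paralog_divergence: float = 0.2
    #: fraction of species carrying an in-species duplicate in paralog
    #: families
    paralog_fraction: float = 0.6
    #: max residues by which the corrupted clustering displaces boundaries
    boundary_jitter: int = 5
    #: fraction of true single-domain clusters falsely split by corruption
    false_split_fraction: float = 0.3
    #: fraction of fused genes left unsplit by corruption
    unsplit_fraction: float = 0.2
    #: fraction of paralog families whose duplicate cluster is pooled into
    #: the ortholog cluster by corruption
    pool_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fusion_fraction",
            "substitution_rate",
            "paralog_fraction",
            "false_split_fraction",
            "unsplit_fraction",
            "pool_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class GroundTruth:
    true_clustering: ClusteringState
    #: fused gene -> residue position of the A/B boundary
    true_boundaries: Dict[str, int]
    #: gene -> "fused" | "split" | "single-domain"
    architecture_labels: Dict[str, str]
    #: family id -> "single" | "fused" | "paralog"
    family_types: Dict[str, str] = field(default_factory=dict)


@dataclass
class Defect:
    kind: str  # false_split | jitter | unsplit | pooled
    target: str  # cluster, gene or family id
    detail: Tuple = ()


@dataclass
class CorruptionResult:
    state: ClusteringState
    defects: List[Defect]


@dataclass
class SyntheticDataset:
    sequences: Dict[str, str]
    truth: GroundTruth
    input_clustering: ClusteringState
    defects: List[Defect]

    def write(self, outdir) -> None:
        import os

        from . import io as dio

        os.makedirs(outdir, exist_ok=True)
        dio.write_fasta(self.sequences, os.path.join(outdir, "proteins.fasta"))
        dio.write_clusters(
            self.input_clustering, os.path.join(outdir, "input.clusters")
        )
        dio.write_clusters(
            self.truth.true_clustering, os.path.join(outdir, "truth.clusters")
        )


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def _random_domain(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _evolve(
    seq: str, rng: np.random.Generator, sub_rate: float, indel_rate: float
) -> str:
    """Apply i.i.d. substitutions then indels (geometric length, mean 2)."""
    chars = list(seq)
    sub_mask = rng.random(len(chars)) < sub_rate
    for i in np.flatnonzero(sub_mask):
        old = chars[i]
        choices = [a for a in AMINO_ACIDS if a != old]
        chars[i] = choices[int(rng.integers(len(choices)))]
    if indel_rate > 0:
        out: List[str] = []
        i = 0
        while i < len(chars):
            if rng.random() < indel_rate:
                length = int(rng.geometric(0.5))
                if rng.random() < 0.5:  # insertion before site i
                    out.extend(
                        rng.choice(list(AMINO_ACIDS), size=length)
                    )
                    out.append(chars[i])
                    i += 1
                else:  # deletion from site i
                    i += length
            else:
                out.append(chars[i])
                i += 1
        chars = out
    if not chars:  # do not let indels erase a domain entirely
        chars = list(seq[:1])
    return "".join(chars)


def _species_ids(n: int) -> List[str]:
    return [f"s{i:02d}" for i in range(1, n + 1)]


def _take(rng: np.random.Generator, items: List[str], count: int) -> List[str]:
    """Deterministically sized random subset, order preserved."""
    count = max(0, min(count, len(items)))
    chosen = rng.choice(len(items), size=count, replace=False)
    keep = set(int(i) for i in chosen)
    return [x for i, x in enumerate(items) if i in keep]


# ---------------------------------------------------------------------------
# family generation
# ---------------------------------------------------------------------------


def generate_family(
    config: SynthConfig,
    rng: np.random.Generator,
    family_id: str,
    family_type: str = "fused",
) -> Tuple[Dict[str, str], GroundTruth]:
    """One protein family plus its piece of the ground truth.

    `family_type` is "single", "fused" (two-domain) or "paralog".
    """
    lo, hi = config.domain_length_range
    species = _species_ids(config.n_species)
    seqs: Dict[str, str] = {}
    truth = GroundTruth(
        ClusteringState(), {}, {}, {family_id: family_type}
    )

    def ev(consensus: str) -> str:
        return _evolve(
            consensus, rng, config.substitution_rate, config.indel_rate
        )

    if family_type in ("single", "paralog"):
        length = int(rng.integers(lo, hi + 1))
        consensus = _random_domain(rng, length)
        main = Cluster(f"{family_id}.A")
        for sp in species:
            gene = f"{sp}:{family_id}a"
            seqs[gene] = ev(consensus)
            main.add(Fragment(gene, 0, len(seqs[gene])))
            truth.architecture_labels[gene] = "single-domain"
        truth.true_clustering.add_cluster(main)
        if family_type == "paralog":
            dup_consensus = _evolve(
                consensus, rng, config.paralog_divergence, config.indel_rate
            )
            dup_species = _take(
                rng,
                species,
                int(round(config.paralog_fraction * len(species))),
            )
            para = Cluster(f"{family_id}.P")
            for sp in dup_species:
                gene = f"{sp}:{family_id}p"
                seqs[gene] = ev(dup_consensus)
                para.add(Fragment(gene, 0, len(seqs[gene])))
                truth.architecture_labels[gene] = "single-domain"
            truth.true_clustering.add_cluster(para)
        return seqs, truth

    if family_type != "fused":
        raise ValueError(f"unknown family type {family_type!r}")

    len_a = int(rng.integers(lo, hi + 1))
    len_b = int(rng.integers(lo, hi + 1))
    cons_a = _random_domain(rng, len_a)
    cons_b = _random_domain(rng, len_b)
    fused_species = _take(
        rng, species, int(round(config.fusion_fraction * len(species)))
    )
    fused_set = set(fused_species)
    cl_a = Cluster(f"{family_id}.A")
    cl_b = Cluster(f"{family_id}.B")
    for sp in species:
        if sp in fused_set:
            part_a, part_b = ev(cons_a), ev(cons_b)
            gene = f"{sp}:{family_id}ab"
            seqs[gene] = part_a + part_b
            boundary = len(part_a)
            cl_a.add(Fragment(gene, 0, boundary))
            cl_b.add(Fragment(gene, boundary, len(seqs[gene])))
            truth.true_boundaries[gene] = boundary
            truth.architecture_labels[gene] = "fused"
        else:
            ga, gb = f"{sp}:{family_id}a", f"{sp}:{family_id}b"
            seqs[ga] = ev(cons_a)
            seqs[gb] = ev(cons_b)
            cl_a.add(Fragment(ga, 0, len(seqs[ga])))
            cl_b.add(Fragment(gb, 0, len(seqs[gb])))
            truth.architecture_labels[ga] = "split"
            truth.architecture_labels[gb] = "split"
    truth.true_clustering.add_cluster(cl_a)
    truth.true_clustering.add_cluster(cl_b)
    return seqs, truth


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------


def corrupt_clustering(
    truth: GroundTruth,
    config: SynthConfig,
    rng: np.random.Generator,
    sequences: Optional[Dict[str, str]] = None,
) -> CorruptionResult:
    """Derive a defective input clustering from the truth.

    Plants, in order: pooled paralog clusters (divide_tree targets), unsplit
    fused genes (create_boundary targets), boundary jitter on the remaining
    fused genes (move_boundary targets), and false splits of single-domain
    clusters (merge targets). Every defect is recorded.
    """
    state = truth.true_clustering.copy()
    defects: List[Defect] = []

    # pool paralog clusters into their ortholog cluster
    paralog_fams = sorted(
        fam for fam, t in truth.family_types.items() if t == "paralog"
    )
    pooled = set(
        _take(
            rng,
            paralog_fams,
            int(round(config.pool_fraction * len(paralog_fams))),
        )
    )
    for fam in pooled:
        pid, aid = f"{fam}.P", f"{fam}.A"
        if pid not in state.clusters:
            continue
        target = state.clusters[aid]
        for frag in state.clusters[pid].members.values():
            target.add(frag)
        state.remove_cluster(pid)
        defects.append(Defect("pooled", fam, (pid, aid)))

    # leave a fraction of fused genes unsplit (full-length fragment kept in
    # the N-terminal cluster)
    fused_genes = sorted(truth.true_boundaries)
    n_unsplit = int(round(config.unsplit_fraction * len(fused_genes)))
    unsplit = set(_take(rng, fused_genes, n_unsplit))
    index = state.gene_index()
    for gene in sorted(unsplit):
        entries = index[gene]
        (cid_n, f_n), (cid_c, f_c) = entries[0], entries[1]
        del state.clusters[cid_c].members[gene]
        state.clusters[cid_n].members[gene] = Fragment(
            gene, f_n.begin, f_c.end
        )
        defects.append(Defect("unsplit", gene, (cid_n, cid_c)))

    # jitter the remaining fused-gene boundaries
    if config.boundary_jitter > 0:
        index = state.gene_index()
        for gene in fused_genes:
            if gene in unsplit:
                continue
            (cid_n, f_n), (cid_c, f_c) = index[gene][0], index[gene][1]
            b = f_n.end
            shift = int(
                rng.integers(-config.boundary_jitter, config.boundary_jitter + 1)
            )
            new_b = min(max(b + shift, f_n.begin + 1), f_c.end - 1)
            if new_b == b:
                continue
            state.clusters[cid_n].members[gene] = Fragment(
                gene, f_n.begin, new_b
            )
            state.clusters[cid_c].members[gene] = Fragment(
                gene, new_b, f_c.end
            )
            defects.append(Defect("jitter", gene, (b, new_b)))

    # falsely split single-domain clusters
    single_clusters = sorted(
        f"{fam}.A"
        for fam, ftype in truth.family_types.items()
        if ftype == "single"
    )
    n_split = int(round(config.false_split_fraction * len(single_clusters)))
    for cid in _take(rng, single_clusters, n_split):
        cluster = state.clusters[cid]
        frac = float(rng.uniform(0.35, 0.65))
        left = Cluster(f"{cid}.L")
        right = Cluster(f"{cid}.R")
        for gene, frag in sorted(cluster.members.items()):
            cut = frag.begin + max(
                1, min(frag.length - 1, int(round(frac * frag.length)))
            )
            left.add(Fragment(gene, frag.begin, cut))
            right.add(Fragment(gene, cut, frag.end))
        state.remove_cluster(cid)
        state.add_cluster(left)
        state.add_cluster(right)
        defects.append(Defect("false_split", cid, (f"{cid}.L", f"{cid}.R")))

    return CorruptionResult(state, defects)


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """The full benchmark: families, ground truth, corrupted input."""
    rng = np.random.default_rng(config.seed)
    sequences: Dict[str, str] = {}
    truth = GroundTruth(ClusteringState(), {}, {}, {})
    for k in range(config.n_families):
        fam = f"F{k:03d}"
        ftype = _TYPE_CYCLE[k % len(_TYPE_CYCLE)]
        seqs, part = generate_family(config, rng, fam, ftype)
        sequences.update(seqs)
        for cluster in part.true_clustering.clusters.values():
            truth.true_clustering.add_cluster(cluster)
        truth.true_boundaries.update(part.true_boundaries)
        truth.architecture_labels.update(part.architecture_labels)
        truth.family_types.update(part.family_types)
    corruption = corrupt_clustering(truth, config, rng, sequences)
    return SyntheticDataset(
        sequences, truth, corruption.state, corruption.defects
    )
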