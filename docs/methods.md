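# Methods

## The problem

Domain-level ortholog clustering assigns *parts* of proteins — orthologous
domains — to clusters, so that a fusion protein A+B can sit in two clusters
at once, split at a domain boundary. Graph-based clusterings of pairwise
similarities (DomClust-style) tend to over-split proteins and to place the
resulting boundaries inconsistently across the members of a family.
`dsprefine` measures the quality of a domain-level clustering directly on
multiple sequence alignments and repairs it by local score optimization.

## The DSP score

For one cluster-pair context we build a multiple alignment
A = (a_ij), i = 1..N_seq, j = 1..N_pos of the full-length proteins involved,
and represent a domain as an indicator matrix D = (d_ij) of the same shape
(d_ij = 1 when cell (i,j) belongs to the domain). The domain-specific
sum-of-pairs score is

    S(A, D) = Σ_{i<i'} [ Σ_j s_dom(a_ij, a_i'j, d_ij, d_i'j)
                         − n_Gopen(a_i·, a_i'·, d_i·, d_i'·) · G_open ]

with

    s_dom(a, a', d, d') = s_mat(a, a')  if b(a)d = 1 and b(a')d' = 1
                        = −G_ext        if exactly one of b(a)d, b(a')d' is 1
                        = 0             otherwise,

where b(a) = 1 iff a is an amino acid, and n_Gopen counts the maximal runs
of columns in which exactly one of the two rows presents an in-domain
residue. Because a run starts wherever the two rows' domains begin or end
in different columns, inconsistent boundary placement is charged like gap
opening; making boundaries coincide recovers exactly those charges, which
is what the refinement operators exploit. Score changes are normalized by
N_seq · N_aa (sequences × total residues of the context alignment) so that
decisions are comparable across families of different size.

Three semantic details are fixed by this implementation:

* **Member pairs only.** The pair sum runs over rows carrying at least one
  in-domain residue. A row entirely outside the domain belongs to a
  different cluster and contributes nothing; this is what makes merging two
  clusters of mutually unrelated members costly (their cross pairs start
  being charged only in the merged domain) and is the property the merge
  threshold relies on.
* **Transparent both-gap columns.** Columns where both rows are gaps
  neither score nor interrupt a gap run. This is the usual pairwise
  projection convention and makes the score invariant under inserting
  all-gap columns.
* **Sign of G_ext.** Gap extension is a penalty: the middle branch of
  s_dom returns −G_ext, so with the full matrix in-domain the DSP score
  reduces to the classical sum-of-pairs score under a
  G_open + L·G_ext gap model (a property the test suite asserts).

## The refinement pipeline

Clusters are *adjacent* when they hold abutting fragments of at least one
shared protein. The pipeline applies five operators in a fixed order; each
examines adjacent pairs (or single clusters for the last) and applies a
modification only under its acceptance rule.

1. **merge** — for each adjacent pair, compare the summed score of the two
   domains with the score after cancelling the splits between them, on the
   same context alignment. Merge when (S′ − S)/(N_seq·N_aa) > S_δ; all
   marked pairs merge at once (union–find over the marked graph). S_δ is
   negative by default: a domain split must *earn* its keep.
2. **merge_divide_tree** — temporarily merge the pair, build a gene tree on
   the context alignment, and evaluate every edge as a candidate root with
   the separation statistic
   t_diff = |g1∩t1| + |g2∩t2| − |g1∩t2| − |g2∩t1| + ||g12∩t1| − |g12∩t2||
   (g1/g2 the clusters' exclusive genes, g12 the shared genes; ties broken
   by longest edge). The winning bipartition defines two full-length
   (domain-architecture) groups; the re-grouping is kept only when the DSP
   score increases. In practice this rescues clusters polluted with
   unrelated single-domain genes.
3. **move_boundary** — move all of a pair's split boundaries to one shared
   alignment column, scanning candidates from the N to the C terminus and
   keeping the best column only on strict improvement. Candidates that
   would empty a domain on any row are skipped. Because coincident
   boundaries cancel all terminal-mismatch charges, the optimum is anchored
   by the unsplit single-domain members of the pair.
4. **create_boundary** — genes of the pair that are not split (they sit in
   only one of the two clusters) are split at the consensus boundary column
   (the modal split column of the already-split members, which
   move_boundary has just made unanimous); the proposed set of new splits
   is accepted jointly iff the score increases. Genes that do not extend
   past the consensus column are skipped.
5. **divide_tree** — for every cluster with ≥ 4 members, build a gene tree
   of the member *fragments*, root it at the position minimizing tree
   height (the midpoint of the leaf diameter path), and divide the cluster
   when the species sets of the two root subtrees overlap by Jaccard
   ≥ R_sp. Division recurses into the subgroups until the rule no longer
   fires. Species overlap between subtrees is the classical signature of a
   duplication above the root.

Every operator iterates in sorted order with deterministic tie-breaks
(score, then leftmost column, then smallest identifier), so reruns are
byte-identical. Each step validates the resulting state (fragments of a
gene never overlap).

## Parameters

| parameter | default | meaning |
|---|---|---|
| G_open | 10 | charge per open gap run (score units) |
| G_ext | 0.5 | charge per in-domain gap column |
| s_mat | BLOSUM45 | substitution matrix (distant homologs) |
| S_δ | −0.05 | normalized score-change threshold for merging |
| R_sp | 0.5 | species-overlap (Jaccard) threshold for division |
| p_cons cutoffs | 70/50/30 % | red/yellow/cyan conservation classes |

These defaults are the published operating point of the method; BLOSUM45
fits the deep divergence typical of cross-species ortholog families.

## Providers

All operators consume alignments and trees through pluggable providers
cached by a content hash of the input sequences (optionally on disk).

* The **built-in aligner** is a deterministic progressive profile aligner:
  sequences are folded into the profile in descending length order, so
  multi-domain proteins lay out the architecture first and single-domain
  proteins settle into their block; profile columns score as
  residue-frequency averages of s_mat and gaps use the same
  G_open/G_ext model as the DSP score. The affine DP runs under numba when
  available, with an equivalent pure-Python fallback.
* The **built-in tree builder** is neighbor joining on p-distances over
  jointly ungapped columns.
* **External providers** wrap any aligner with a Clustal-Omega-style CLI
  (`clustalo -i {input} -o {output}`, `mafft --auto {input} > {output}`)
  and any tree builder with a FastTree-style CLI. Their absence never
  breaks the built-in path; tests use only the built-in providers.

## Evaluation

Two clusterings over a shared gene universe are compared by a bipartite
overlap graph (an edge wherever fragments of one gene share ≥ 1 residue).
N^1to1 counts edges whose both endpoints have degree one; r̄_over averages
r_over = |c∩d| / max(|c|,|d|) over all overlapping fragment pairs. The
inclusion classes (equivalent / supergroup / subgroup) reported by
`classify_inclusion` are a reconstruction based on 80% containment of the
smaller fragment, not a published definition.

## The synthetic benchmark

The generator plants known targets for every operator: per block of five
families, two single-domain families, two two-domain families (a fixed
fraction of species carry the fused A+B architecture, the rest separate A
and B proteins), and one paralog family (a fraction of species carry an
in-species duplicate descending from a single pre-speciation duplication).
Sequences evolve from a uniform-random family consensus on a star
phylogeny with i.i.d. substitutions (rate 0.1/site), indels
(0.01/site, geometric lengths of mean 2), and an extra 0.2/site on the
duplication branch. The corrupter then displaces fused-gene boundaries by
up to 5 residues, leaves 20% of fused genes unsplit, falsely splits 30% of
the single-domain clusters, and pools the duplicate clusters into their
ortholog clusters — recording every defect. Species counts per condition
are deterministic rounds of the fractions, so the planted structure does
not drift with the seed. The default problem size (20 families × 10
species) keeps a full pipeline run to a few seconds while every operator
still has several targets.

What the benchmark does *not* emulate: realistic amino-acid composition or
rate heterogeneity, non-star gene trees, horizontal transfer,
tandem-repeat domains, and the scale of real pan-genome datasets. Passing
on it demonstrates that the operators optimize the score and recover the
planted structure under moderate divergence — not that the method's
published behavior on curated reference databases is reproduced.

Two behaviors observed at these conditions are worth knowing. First, when
a large share of a family's fused genes are unsplit in the input, the DSP
score genuinely favors merging that family's two domain clusters (the
unsplit members make the pair look like one domain); the merge step then
fires before the boundary steps could repair the family. Second,
one-to-one counts are insensitive to boundary moves that land within a
residue or two of the reference, since any residual overlap keeps the
extra graph edge; the mean overlap ratio is the sensitive measure there.

## Numerical choices and edge cases

* Scores accumulate in double precision; candidate columns are compared
  with a 1e−12 slack and strict-improvement acceptance uses 1e−9, so ties
  resolve to the leftmost column.
* Cluster files are 1-based inclusive on disk, 0-based half-open in
  memory; per-gene boundary gaps/overlaps of ≤ 2 residues are snapped to a
  shared boundary on read (and logged); larger overlaps are rejected.
* NJ branch lengths are clamped at zero; degree-2 nodes from rooted Newick
  input are spliced out.
* Pairs with fewer than 3 context genes skip tree-based steps; clusters
  with < 4 members skip division; provider failures skip the pair with a
  warning rather than aborting the run.
* Merging can, in principle, join non-adjacent fragments of one gene
  (through a transitive chain); the fragments are then coalesced across
  the gap with a warning, keeping the one-fragment-per-gene invariant.

## Known limitations

* The built-in aligner is O(L²) per profile merge with a fixed join order;
  for large or deeply diverged families an external aligner will be both
  faster and more accurate.
* move_boundary moves one shared column per pair; families whose true
  boundaries are genuinely non-homologous across members are out of reach
  of this operator by design.
* divide_tree trusts the tree: a misplaced leaf (easy to produce with
  p-distance NJ at low divergence) moves that gene to the wrong subgroup.
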