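import numpy as np
import pytest

from dsprefine.core import (
    Cluster,
    ClusteringState,
    Fragment,
    ScoreParams,
    indicator_for_fragments,
    validate_state,
)
from dsprefine.dsp import DspEngine
from dsprefine.refine import (
    AlignmentProvider,
    BuiltinAligner,
    TreeProvider,
    create_boundary_step,
    divide_tree_step,
    find_adjacent_pairs,
    merge_divide_tree_step,
    merge_step,
    move_boundary_step,
    run_pipeline,
)
from dsprefine.synth import SynthConfig, generate_dataset

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_seq(rng, n):
    return "".join(rng.choice(list(AA), size=n))


def mutate(seq, rng, n_sub):
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(n_sub, len(chars)), replace=False):
        chars[pos] = AA[int(rng.integers(20))]
    return "".join(chars)


def make_state(entries):
    state = ClusteringState()
    for cid, gene, b, e in entries:
        if cid not in state.clusters:
            state.add_cluster(Cluster(cid))
        state.clusters[cid].add(Fragment(gene, b, e))
    return state


@pytest.fixture(scope="module")
def small_dataset():
    return generate_dataset(SynthConfig(seed=1, n_families=5))


@pytest.fixture(scope="module")
def small_provider(small_dataset):
    return AlignmentProvider(small_dataset.sequences)


class TestFindAdjacentPairs:
    def test_split_gene_links_its_two_clusters(self):
        state = make_state([("X", "a:g", 0, 100), ("Y", "a:g", 100, 250)])
        pairs = find_adjacent_pairs(state)
        assert len(pairs) == 1
        assert (pairs[0].cluster_a, pairs[0].cluster_b) == ("X", "Y")
        assert pairs[0].shared_genes == ["a:g"]
        assert pairs[0].a_is_nterm["a:g"] is True

    def test_no_split_genes_gives_empty_list(self):
        state = make_state([("X", "a:g1", 0, 100), ("Y", "a:g2", 0, 100)])
        assert find_adjacent_pairs(state) == []

    def test_three_fragments_link_only_consecutive_clusters(self):
        state = make_state(
            [("X", "a:g", 0, 50), ("Y", "a:g", 50, 100), ("Z", "a:g", 100, 150)]
        )
        pairs = find_adjacent_pairs(state)
        assert [(p.cluster_a, p.cluster_b) for p in pairs] == [
            ("X", "Y"),
            ("Y", "Z"),
        ]

    def test_non_abutting_fragments_are_not_adjacent(self):
        state = make_state([("X", "a:g", 0, 50), ("Y", "a:g", 60, 100)])
        assert find_adjacent_pairs(state) == []


class TestMergeStep:
    def test_consistent_split_of_identical_sequences_is_merged(self, rng):
        seq = random_seq(rng, 60)
        seqs = {f"s{i}:g": seq for i in range(1, 6)}
        state = make_state(
            [("L", g, 0, 30) for g in seqs] + [("R", g, 30, 60) for g in seqs]
        )
        report = merge_step(state, AlignmentProvider(seqs))
        assert report.n_examined == 1 and report.n_applied == 1
        assert len(report.state_after) == 1
        (cluster,) = report.state_after.clusters.values()
        assert all(
            (f.begin, f.end) == (0, 60) for f in cluster.members.values()
        )

    def test_unrelated_clusters_sharing_one_chimera_stay_split(self, rng):
        cons_x, cons_y = random_seq(rng, 60), random_seq(rng, 50)
        seqs = {}
        entries = []
        for i in range(1, 5):
            gx, gy = f"s{i}:x", f"s{i}:y"
            seqs[gx] = mutate(cons_x, rng, 4)
            seqs[gy] = mutate(cons_y, rng, 4)
            entries.append(("CX", gx, 0, len(seqs[gx])))
            entries.append(("CY", gy, 0, len(seqs[gy])))
        chim = "s5:chimera"
        seqs[chim] = mutate(cons_x, rng, 4) + mutate(cons_y, rng, 4)
        entries.append(("CX", chim, 0, 60))
        entries.append(("CY", chim, 60, len(seqs[chim])))
        state = make_state(entries)
        report = merge_step(state, AlignmentProvider(seqs))
        assert report.n_examined == 1 and report.n_applied == 0
        assert set(report.state_after.clusters) == {"CX", "CY"}

    def test_marked_chain_collapses_into_one_cluster(self, rng):
        seq = random_seq(rng, 90)
        seqs = {f"s{i}:g": seq for i in range(1, 5)}
        entries = []
        for g in seqs:
            entries += [("X", g, 0, 30), ("Y", g, 30, 60), ("Z", g, 60, 90)]
        state = make_state(entries)
        report = merge_step(state, AlignmentProvider(seqs))
        assert report.n_applied == 2
        assert len(report.state_after) == 1
        assert report.state_after.total_residues() == state.total_residues()

    def test_threshold_monotonicity(self, small_dataset, small_provider):
        state = small_dataset.input_clustering
        n_pairs = len(find_adjacent_pairs(state))
        assert n_pairs > 0
        merge_all = merge_step(
            state, small_provider, ScoreParams(merge_threshold=-np.inf)
        )
        merge_none = merge_step(
            state, small_provider, ScoreParams(merge_threshold=np.inf)
        )
        assert merge_all.n_applied == n_pairs
        assert merge_none.n_applied == 0
        assert merge_none.state_after == state


class TestMoveBoundaryStep:
    def _fixture(self, rng, cuts, n_anchors=3):
        """Identical 80-mers split at per-gene positions `cuts`, anchored by
        single-domain members ending exactly at residue 40."""
        seq = random_seq(rng, 80)
        seqs = {}
        entries = []
        for i, cut in enumerate(cuts, start=1):
            g = f"s{i}:ab"
            seqs[g] = seq
            entries += [("A", g, 0, cut), ("B", g, cut, 80)]
        for i in range(1, n_anchors + 1):
            ga, gb = f"t{i}:a", f"t{i}:b"
            seqs[ga] = seq[:40]
            seqs[gb] = seq[40:]
            entries += [("A", ga, 0, 40), ("B", gb, 0, 40)]
        return seqs, make_state(entries)

    def test_scattered_boundaries_move_to_the_planted_column(self, rng):
        cuts = [35, 38, 40, 42, 45]
        seqs, state = self._fixture(rng, cuts)
        report = move_boundary_step(state, AlignmentProvider(seqs))
        assert report.n_applied == 1
        after = report.state_after
        for i in range(1, 6):
            assert after.clusters["A"].members[f"s{i}:ab"].end == 40
            assert after.clusters["B"].members[f"s{i}:ab"].begin == 40
        assert after.total_residues() == state.total_residues()

    def test_already_optimal_configuration_is_unchanged(self, rng):
        seqs, state = self._fixture(rng, [40, 40, 40, 40])
        report = move_boundary_step(state, AlignmentProvider(seqs))
        assert report.n_applied == 0
        assert report.state_after == state

    def test_chosen_column_maximizes_dsp_over_exhaustive_scan(self, rng):
        cuts = [36, 39, 41, 44]
        seqs, state = self._fixture(rng, cuts, n_anchors=2)
        provider = AlignmentProvider(seqs)
        report = move_boundary_step(state, provider)
        # exhaustive rescan: every candidate column of the pair context
        pair = find_adjacent_pairs(state)[0]
        genes = sorted(
            set(state.clusters["A"].members) | set(state.clusters["B"].members)
        )
        aln = provider.full_length(genes)
        engine = DspEngine(aln, ScoreParams())
        shared = pair.shared_genes
        best = -np.inf
        for c in range(1, aln.n_pos):
            frags_a, frags_b = [], []
            ok = True
            for g in genes:
                row = aln.row_index(g)
                cols = aln.residue_columns(row)
                if g in shared:
                    k = int((cols < c).sum())
                    if k == 0 or k == len(cols):
                        ok = False
                        break
                    frags_a.append(Fragment(g, 0, k))
                    frags_b.append(Fragment(g, k, len(cols)))
                elif g in state.clusters["A"].members:
                    frags_a.append(state.clusters["A"].members[g])
                else:
                    frags_b.append(state.clusters["B"].members[g])
            if not ok:
                continue
            score = engine.score_indicator(
                indicator_for_fragments(aln, frags_a)
            ) + engine.score_indicator(indicator_for_fragments(aln, frags_b))
            best = max(best, score)
        after = report.state_after
        got_frags_a = list(after.clusters["A"].members.values())
        got_frags_b = list(after.clusters["B"].members.values())
        got = engine.score_indicator(
            indicator_for_fragments(aln, got_frags_a)
        ) + engine.score_indicator(indicator_for_fragments(aln, got_frags_b))
        assert got == pytest.approx(best)

    def test_never_decreases_the_summed_score(self, small_dataset, small_provider):
        state = small_dataset.input_clustering
        report = move_boundary_step(state, small_provider)
        assert all(change >= 0.0 for change in report.score_changes)


class TestCreateBoundaryStep:
    def _fixture(self, rng, n_split=8, n_unsplit=2):
        seq = random_seq(rng, 80)
        seqs = {}
        entries = []
        for i in range(1, n_split + 1):
            g = f"s{i}:ab"
            seqs[g] = seq
            entries += [("A", g, 0, 40), ("B", g, 40, 80)]
        for i in range(1, n_unsplit + 1):
            g = f"u{i}:ab"
            seqs[g] = seq
            entries.append(("A", g, 0, 80))
        return seqs, make_state(entries)

    def test_unsplit_fused_genes_are_split_at_the_consensus(self, rng):
        seqs, state = self._fixture(rng)
        report = create_boundary_step(state, AlignmentProvider(seqs))
        assert report.n_applied == 1
        after = report.state_after
        for i in (1, 2):
            g = f"u{i}:ab"
            assert after.clusters["A"].members[g].end == 40
            assert after.clusters["B"].members[g] == Fragment(g, 40, 80)
        assert after.total_residues() == state.total_residues()
        assert report.score_changes[0] > 0

    def test_candidate_not_spanning_the_boundary_is_skipped(self, rng):
        seqs, state = self._fixture(rng, n_unsplit=0)
        # an A-only member that ends exactly at the boundary: no residue on
        # the C side, so it must not be split
        seq40 = seqs["s1:ab"][:40]
        seqs = dict(seqs, **{"v1:a": seq40})
        state = state.copy()
        state.clusters["A"].add(Fragment("v1:a", 0, 40))
        report = create_boundary_step(state, AlignmentProvider(seqs))
        after = report.state_after
        assert after.clusters["A"].members["v1:a"] == Fragment("v1:a", 0, 40)
        assert "v1:a" not in after.clusters["B"].members

    def test_no_unsplit_members_is_a_noop(self, rng):
        seqs, state = self._fixture(rng, n_unsplit=0)
        report = create_boundary_step(state, AlignmentProvider(seqs))
        assert report.n_applied == 0
        assert report.state_after == state


class TestMergeDivideTreeStep:
    def test_contaminated_cluster_is_regrouped_by_architecture(self, rng):
        """A domain cluster polluted with unrelated single-domain genes is
        re-divided into {fused proteins} and {the unrelated genes}."""
        cons_a, cons_b = random_seq(rng, 40), random_seq(rng, 35)
        seqs = {}
        entries = []
        for i in range(1, 5):
            g = f"s{i}:ab"
            seqs[g] = mutate(cons_a, rng, 3) + mutate(cons_b, rng, 3)
            entries += [("CA", g, 0, 40), ("CB", g, 40, len(seqs[g]))]
        for i in range(1, 5):
            g = f"u{i}:x"
            seqs[g] = random_seq(rng, 40)
            entries.append(("CA", g, 0, 40))
        state = make_state(entries)
        report = merge_divide_tree_step(
            state, AlignmentProvider(seqs), TreeProvider()
        )
        assert report.n_applied == 1
        after = report.state_after
        groups = sorted(
            frozenset(c.members) for c in after.clusters.values()
        )
        assert frozenset(f"s{i}:ab" for i in range(1, 5)) in groups
        assert frozenset(f"u{i}:x" for i in range(1, 5)) in groups
        # fused proteins are full-length in the re-grouped cluster
        for cluster in after.clusters.values():
            for gene, frag in cluster.members.items():
                assert (frag.begin, frag.end) == (0, len(seqs[gene]))

    def test_properly_split_two_domain_family_is_rejected(self, rng):
        cons_a, cons_b = random_seq(rng, 40), random_seq(rng, 35)
        seqs = {}
        entries = []
        for i in range(1, 4):
            g = f"s{i}:ab"
            seqs[g] = mutate(cons_a, rng, 3) + mutate(cons_b, rng, 3)
            entries += [("CA", g, 0, 40), ("CB", g, 40, len(seqs[g]))]
        for i in range(4, 8):
            ga, gb = f"s{i}:a", f"s{i}:b"
            seqs[ga] = mutate(cons_a, rng, 3)
            seqs[gb] = mutate(cons_b, rng, 3)
            entries += [("CA", ga, 0, 40), ("CB", gb, 0, 35)]
        state = make_state(entries)
        report = merge_divide_tree_step(
            state, AlignmentProvider(seqs), TreeProvider()
        )
        assert report.n_applied == 0
        assert report.state_after == state


class TestDivideTreeStep:
    def _family(self, rng, consensus, species, tag):
        return {
            f"{sp}:{tag}": mutate(consensus, rng, 3) for sp in species
        }

    def test_pooled_paralog_families_are_divided(self, rng):
        cons = random_seq(rng, 60)
        cons_dup = mutate(cons, rng, 25)
        species = [f"s{i}" for i in range(1, 5)]
        orig = self._family(rng, cons, species, "g")
        dups = self._family(rng, cons_dup, species, "p")
        seqs = {**orig, **dups}
        entries = [("C", g, 0, len(s)) for g, s in sorted(seqs.items())]
        state = make_state(entries)
        report = divide_tree_step(
            state, AlignmentProvider(seqs), TreeProvider()
        )
        assert report.n_applied == 1
        groups = sorted(
            frozenset(c.members) for c in report.state_after.clusters.values()
        )
        assert frozenset(orig) in groups and frozenset(dups) in groups

    def test_single_copy_family_is_kept(self, rng):
        cons = random_seq(rng, 60)
        species = [f"s{i}" for i in range(1, 7)]
        seqs = self._family(rng, cons, species, "g")
        state = make_state([("C", g, 0, len(s)) for g, s in sorted(seqs.items())])
        report = divide_tree_step(
            state, AlignmentProvider(seqs), TreeProvider()
        )
        assert report.n_applied == 0
        assert report.state_after == state

    def test_overlap_exactly_at_threshold_divides(self, rng):
        # duplicates in half the species: Jaccard overlap exactly 0.5
        cons = random_seq(rng, 60)
        cons_dup = mutate(cons, rng, 25)
        orig = self._family(rng, cons, ["s1", "s2", "s3", "s4"], "g")
        dups = self._family(rng, cons_dup, ["s1", "s2"], "p")
        seqs = {**orig, **dups}
        state = make_state(
            [("C", g, 0, len(s)) for g, s in sorted(seqs.items())]
        )
        report = divide_tree_step(
            state, AlignmentProvider(seqs), TreeProvider()
        )
        assert report.n_applied == 1


class TestRunPipeline:
    def test_perfect_input_is_a_fixed_point(self):
        ds = generate_dataset(
            SynthConfig(
                seed=2,
                n_families=5,
                boundary_jitter=0,
                false_split_fraction=0.0,
                unsplit_fraction=0.0,
                pool_fraction=0.0,
            )
        )
        reports = run_pipeline(
            ds.input_clustering, AlignmentProvider(ds.sequences), TreeProvider()
        )
        assert all(r.n_applied == 0 for r in reports)
        assert reports[-1].state_after == ds.truth.true_clustering

    def test_empty_clustering_produces_empty_reports(self):
        reports = run_pipeline(
            ClusteringState(), AlignmentProvider({}), TreeProvider()
        )
        assert len(reports) == 5
        assert all(r.n_examined == 0 and r.n_applied == 0 for r in reports)

    def test_every_step_preserves_state_validity(
        self, small_dataset, small_provider
    ):
        reports = run_pipeline(
            small_dataset.input_clustering, small_provider, TreeProvider()
        )
        for report in reports:
            assert (
                validate_state(report.state_after, small_dataset.sequences)
                == []
            )

    def test_step_subset_runs_only_those_steps(
        self, small_dataset, small_provider
    ):
        reports = run_pipeline(
            small_dataset.input_clustering,
            small_provider,
            TreeProvider(),
            steps=["merge"],
        )
        assert [r.step_name for r in reports] == ["merge"]

    def test_unknown_step_name_is_rejected(self, small_provider):
        with pytest.raises(ValueError, match="unknown steps"):
            run_pipeline(
                ClusteringState(), small_provider, TreeProvider(), steps=["x"]
            )
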