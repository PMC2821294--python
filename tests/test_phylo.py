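import numpy as np
import pytest

from efpmod.phylo import (
    AA_ORDER,
    DistanceMatrix,
    JTT_FREQS,
    ProteinAlignment,
    bootstrap_trees,
    consensus_support,
    jtt_distance,
    jtt_distance_matrix,
    jtt_transition,
    majority_rule_consensus,
    nj_tree,
    patristic_matrix,
    robinson_foulds,
    split_subfamilies,
)
from efpmod.synthetic_data import evolve_alignment, two_clade_tree

from oracles import grid_jtt_distance, random_additive_matrix


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        assert np.allclose(jtt_transition(0.0), np.eye(20), atol=1e-12)

    def test_rows_are_stochastic(self):
        for t in (0.01, 0.3, 1.0, 5.0):
            assert np.allclose(jtt_transition(t).sum(axis=1), 1.0, atol=1e-10)

    def test_ergodic_limit_is_stationary(self):
        P = jtt_transition(50.0)
        for row in P:
            assert np.allclose(row, JTT_FREQS, atol=1e-6)

    def test_chapman_kolmogorov(self):
        for s, t in [(0.1, 0.2), (0.5, 1.3), (0.05, 2.0)]:
            lhs = jtt_transition(s) @ jtt_transition(t)
            assert np.allclose(lhs, jtt_transition(s + t), atol=1e-8)

    def test_detailed_balance(self):
        P = jtt_transition(0.7)
        flux = JTT_FREQS[:, None] * P
        assert np.allclose(flux, flux.T, atol=1e-10)

    def test_one_expected_substitution_per_unit_time(self):
        # d/dt of substitution probability at t=0 equals 1
        eps = 1e-7
        P = jtt_transition(eps)
        rate = (1 - (JTT_FREQS * np.diag(P)).sum()) / eps
        assert rate == pytest.approx(1.0, rel=1e-4)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            jtt_transition(-0.1)


class TestDistance:
    def test_identical_sequences_give_zero(self):
        row = "".join(AA_ORDER[i % 20] for i in range(100))
        assert jtt_distance(row, row) <= 1e-5

    def test_symmetric(self, rng):
        a = "".join(AA_ORDER[i] for i in rng.integers(0, 20, 120))
        b = "".join(AA_ORDER[i] for i in rng.integers(0, 20, 120))
        assert jtt_distance(a, b) == pytest.approx(jtt_distance(b, a), abs=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        tree, _ = two_clade_tree(n_per_clade=2, intra=0.2, split=0.6)
        aln = evolve_alignment(tree, 150, seed=5)
        for i, j in [(0, 1), (0, 2), (1, 3)]:
            mine = jtt_distance(aln.rows[i], aln.rows[j])
            oracle = grid_jtt_distance(aln.rows[i], aln.rows[j])
            assert mine == pytest.approx(oracle, abs=2e-4)

    def test_gap_columns_excluded_pairwise(self):
        a = "ARNDCQEGHILKMFPSTWYV" * 3
        b = "-" + a[1:]
        d_full = jtt_distance(a, a)
        d_gap = jtt_distance(a, b)
        assert d_gap == pytest.approx(d_full, abs=1e-5)

    def test_no_shared_columns_is_error(self):
        with pytest.raises(ValueError):
            jtt_distance("AA--", "--AA")

    def test_matrix_route_agrees_with_scalar_route(self):
        tree, _ = two_clade_tree(n_per_clade=2, intra=0.15, split=0.5)
        aln = evolve_alignment(tree, 200, seed=9)
        D = jtt_distance_matrix(aln)
        for i in range(aln.n_taxa):
            for j in range(i + 1, aln.n_taxa):
                assert D.d[i, j] == pytest.approx(
                    jtt_distance(aln.rows[i], aln.rows[j]), abs=1e-4
                )

    def test_parameter_recovery_under_simulation(self):
        # distances estimated from JTT-simulated pairs recover the truth
        import dendropy

        true_t = 0.5
        estimates = []
        for seed in range(12):
            tns = dendropy.TaxonNamespace(["a", "b"])
            tree = dendropy.Tree(taxon_namespace=tns)
            for label in ("a", "b"):
                leaf = dendropy.Node(taxon=tns.get_taxon(label))
                tree.seed_node.add_child(leaf)
                leaf.edge.length = true_t / 2
            aln = evolve_alignment(tree, 500, seed=seed)
            estimates.append(jtt_distance(aln.rows[0], aln.rows[1]))
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - true_t) < 3 * max(se, 1e-3)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(taxa=["A", "B", "C"],
                           d=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        tree = nj_tree(D)
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxon_additive_topology_and_lengths(self):
        # tree ((A:1,B:1):1,(C:1,D:1):1): AB=2, CD=2, cross=4
        d = np.array([
            [0, 2, 4, 4],
            [2, 0, 4, 4],
            [4, 4, 0, 2],
            [4, 4, 2, 0.0],
        ])
        D = DistanceMatrix(taxa=list("ABCD"), d=d)
        tree = nj_tree(D)
        P = patristic_matrix(tree)
        assert np.allclose(P.d, d, atol=1e-12)
        from efpmod.phylo import _bipartitions

        splits = set(_bipartitions(tree))
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_random_additive_matrices_recovered_exactly(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 9))
            taxa, d = random_additive_matrix(n, rng)
            tree = nj_tree(DistanceMatrix(taxa=taxa, d=d))
            P = patristic_matrix(tree)
            order = [P.taxa.index(t) for t in taxa]
            assert np.max(np.abs(P.d[np.ix_(order, order)] - d)) < 1e-9

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(taxa=["a", "b"], d=np.array([[0, 1], [2, 0.0]]))

    def test_topology_agrees_with_scikit_bio(self, rng):
        import dendropy
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        n = 8
        taxa, d = random_additive_matrix(n, rng)
        noise = rng.uniform(0, 0.01, size=(n, n))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        dn = d + noise
        mine = nj_tree(DistanceMatrix(taxa=taxa, d=dn))
        theirs_newick = str(skbio_nj(SkbioDM(dn, ids=taxa)))
        tns = mine.taxon_namespace
        theirs = dendropy.Tree.get(
            data=theirs_newick, schema="newick", taxon_namespace=tns
        )
        assert robinson_foulds(mine, theirs) == 0


class TestBootstrapAndConsensus:
    def test_same_seed_reproducible(self):
        tree, _ = two_clade_tree(n_per_clade=3, intra=0.2, split=0.8)
        aln = evolve_alignment(tree, 80, seed=3)
        a = bootstrap_trees(aln, n_reps=4, seed=77)
        b = bootstrap_trees(aln, n_reps=4, seed=77)
        for ta, tb in zip(a, b):
            assert ta.as_string(schema="newick") == tb.as_string(schema="newick")

    def test_single_column_pattern_gives_identical_trees(self):
        aln = ProteinAlignment(
            taxa=["a", "b", "c", "d"],
            rows=["AAAA", "RRRR", "NNNN", "DDDD"],
        )
        reps = bootstrap_trees(aln, n_reps=5, seed=1)
        newicks = {t.as_string(schema="newick") for t in reps}
        assert len(newicks) == 1

    def test_n_reps_one(self):
        tree, _ = two_clade_tree(n_per_clade=2, intra=0.2, split=0.5)
        aln = evolve_alignment(tree, 60, seed=2)
        assert len(bootstrap_trees(aln, n_reps=1, seed=0)) == 1

    def test_identical_replicates_give_full_support(self, rng):
        taxa, d = random_additive_matrix(6, rng)
        main = nj_tree(DistanceMatrix(taxa=taxa, d=d))
        reps = [nj_tree(DistanceMatrix(taxa=taxa, d=d)) for _ in range(10)]
        annotated = consensus_support(main, reps)
        supports = [n.support for n in annotated.preorder_node_iter()
                    if getattr(n, "support", None) is not None]
        assert supports and all(s == 10 for s in supports)

    def test_taxon_mismatch_rejected(self, rng):
        taxa, d = random_additive_matrix(5, rng)
        main = nj_tree(DistanceMatrix(taxa=taxa, d=d))
        other_taxa, other_d = random_additive_matrix(5, rng)
        other = nj_tree(DistanceMatrix(taxa=[t + "_x" for t in other_taxa], d=other_d))
        with pytest.raises(ValueError):
            consensus_support(main, [other])

    def test_deep_split_recovers_high_support(self):
        tree, clade_of = two_clade_tree(n_per_clade=5, intra=0.15, split=1.2)
        aln = evolve_alignment(tree, 118, seed=13)
        main = nj_tree(jtt_distance_matrix(aln))
        reps = bootstrap_trees(aln, n_reps=50, seed=13)
        main = consensus_support(main, reps)
        from efpmod.phylo import _bipartitions

        clade_a = frozenset(t for t, c in clade_of.items() if c == "yjeK")
        splits = _bipartitions(main)
        all_taxa = frozenset(clade_of)
        key = min(clade_a, all_taxa - clade_a, key=lambda s: (len(s), sorted(s)))
        assert key in splits
        assert splits[key].support > 45  # > 90% of 50 replicates

    def test_majority_rule_consensus_contains_stable_split(self, rng):
        taxa, d = random_additive_matrix(6, rng)
        reps = [nj_tree(DistanceMatrix(taxa=taxa, d=d)) for _ in range(4)]
        cons = majority_rule_consensus(reps)
        assert {l.taxon.label for l in cons.leaf_node_iter()} == set(taxa)


class TestNoiselessRecovery:
    def test_generating_topology_recovered_from_long_alignment(self):
        import dendropy

        newick = (
            "((a:0.2,b:0.2):0.3,(c:0.2,d:0.2):0.3,"
            "((e:0.2,f:0.2):0.3,(g:0.2,h:0.2):0.3):0.3);"
        )
        generating = dendropy.Tree.get(data=newick, schema="newick")
        aln = evolve_alignment(generating, 3000, seed=21)
        inferred = nj_tree(jtt_distance_matrix(aln))
        generating = dendropy.Tree.get(
            data=newick, schema="newick",
            taxon_namespace=inferred.taxon_namespace,
        )
        assert robinson_foulds(inferred, generating) == 0

    def test_nj_on_exact_patristic_distances_is_lossless(self, rng):
        # noiseless distances: patristic matrix of the inferred tree feeds
        # a second NJ round, which must reproduce the tree exactly
        taxa, d = random_additive_matrix(7, rng)
        first = nj_tree(DistanceMatrix(taxa=taxa, d=d))
        again = nj_tree(patristic_matrix(first))
        assert robinson_foulds(first, again) == 0


class TestSubfamilySplit:
    def make_supported_tree(self, clade_of, intra=0.1, split=2.0, columns=400, seed=4):
        n = len(clade_of) // 2
        tree, _ = two_clade_tree(n_per_clade=n, intra=intra, split=split)
        aln = evolve_alignment(tree, columns, seed=seed)
        main = nj_tree(jtt_distance_matrix(aln))
        reps = bootstrap_trees(aln, n_reps=10, seed=5)
        return consensus_support(main, reps)

    def test_two_clean_clades_recovered(self):
        tree, clade_of = two_clade_tree(n_per_clade=4)
        contexts = {t: {"efp"} if c == "yjeK" else {"ablB"} for t, c in clade_of.items()}
        main = self.make_supported_tree(clade_of)
        parts = split_subfamilies(main, contexts)
        by_ctx = {p.dominant_context: set(p.members) for p in parts}
        assert by_ctx["efp"] == {t for t, c in clade_of.items() if c == "yjeK"}
        assert by_ctx["ablB"] == {t for t, c in clade_of.items() if c == "ablA"}

    def test_all_empty_contexts_single_unassigned(self):
        tree, clade_of = two_clade_tree(n_per_clade=3)
        main = self.make_supported_tree(clade_of, seed=6)
        parts = split_subfamilies(main, {t: set() for t in clade_of})
        assert len(parts) == 1
        assert parts[0].dominant_context is None
        assert set(parts[0].members) == set(clade_of)

    def test_mislabeled_taxon_reported_as_conflict(self):
        tree, clade_of = two_clade_tree(n_per_clade=4)
        contexts = {t: {"efp"} if c == "yjeK" else {"ablB"} for t, c in clade_of.items()}
        offender = "yjeK_2"
        contexts[offender] = {"ablB"}   # planted wrong label inside clean clade
        main = self.make_supported_tree(clade_of)
        parts = split_subfamilies(main, contexts)
        efp_part = next(p for p in parts if p.dominant_context == "efp")
        assert offender in efp_part.conflicts
        assert set(efp_part.members) >= {t for t, c in clade_of.items()
                                         if c == "yjeK" and t != offender}

    def test_exhaustive_single_mislabel_small_trees(self, rng):
        # every possible single mislabel position on trees of <= 8 taxa
        for n_per_clade in (3, 4):
            tree, clade_of = two_clade_tree(n_per_clade=n_per_clade)
            main = self.make_supported_tree(clade_of, seed=n_per_clade)
            taxa = sorted(clade_of)
            for offender in taxa:
                contexts = {
                    t: {"efp"} if clade_of[t] == "yjeK" else {"ablB"}
                    for t in taxa
                }
                wrong = "ablB" if clade_of[offender] == "yjeK" else "efp"
                contexts[offender] = {wrong}
                parts = split_subfamilies(main, contexts)
                conflicts = {m for p in parts for m in p.conflicts}
                assert offender in conflicts

    def test_missing_context_entry_rejected(self):
        tree, clade_of = two_clade_tree(n_per_clade=3)
        main = self.make_supported_tree(clade_of, seed=8)
        with pytest.raises(ValueError):
            split_subfamilies(main, {})
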