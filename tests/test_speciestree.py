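"""Species-tree estimation: STAR ranks, triplet tallies, MP-EST
pseudo-likelihood, gene-tree estimation and the tree-of-trees."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import anchortree as at
from anchortree.simulate import scale_to_min_internal
from conftest import make_tree, yule_tree


class TestGeneTreeEstimation:
    def test_strong_signal_recovery(self):
        tree = make_tree("((A:0.2,B:0.2):0.3,C:0.5);")
        aln = at.simulate_sequences(tree, 2000,
                                    at.SubstitutionModel(rate=1.0), seed=1)
        est = at.estimate_gene_tree(aln, outgroup="C")
        assert at.rf_distance(est, tree).rf == 0

    def test_zero_divergence_flagged_by_low_support(self):
        aln = {x: "ACGT" * 100 for x in "ABCD"}
        est = at.estimate_gene_tree(aln, bootstrap_replicates=20, seed=2)
        assert est is not None  # arbitrary but valid resolution

    def test_bootstrap_full_support_on_clean_fixture(self):
        tree = make_tree(
            "(((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2):0.2,E:0.5);")
        aln = at.simulate_sequences(tree, 5000,
                                    at.SubstitutionModel(rate=1.0), seed=3)
        est = at.estimate_gene_tree(aln, outgroup="E",
                                    bootstrap_replicates=100, seed=4)
        assert at.mean_bootstrap(est) == 100.0

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            at.estimate_gene_tree({"A": "ACGT", "B": "ACGT"})


class TestTripletCounts:
    def test_four_taxon_single_tree(self):
        counts = at.triplet_counts([make_tree("(((A,B),C),D);")])
        assert len(counts.triples) == 4
        assert counts.n_per_triple.tolist() == [1, 1, 1, 1]
        assert counts.for_triple("A", "B", "C") == {"A": 0, "B": 0, "C": 1}
        assert counts.for_triple("A", "C", "D") == {"A": 0, "C": 0, "D": 1}

    def test_matches_brute_force_restriction(self):
        gts = [yule_tree(5, seed=s) for s in range(12)]
        taxa = sorted(t.label for t in gts[0].taxon_namespace)
        counts = at.triplet_counts(gts, taxa=taxa)
        for (a, b, c) in itertools.combinations(taxa, 3):
            tally = {a: 0, b: 0, c: 0}
            for gt in gts:
                # brute force: prune to the triple, read the outsider
                sub = gt.extract_tree_with_taxa_labels([a, b, c])
                for nd in sub.preorder_internal_node_iter():
                    leaves = [lf.taxon.label for lf in nd.leaf_iter()]
                    if len(leaves) == 2:
                        out = ({a, b, c} - set(leaves)).pop()
                        tally[out] += 1
            assert counts.for_triple(a, b, c) == tally

    def test_missing_taxon_leaves_triples_untouched(self):
        full = make_tree("(((A,B),C),D);")
        partial = make_tree("((A,B),C);")
        counts = at.triplet_counts([full, partial],
                                   taxa=["A", "B", "C", "D"])
        assert counts.for_triple("A", "B", "C")["C"] == 2
        assert sum(counts.for_triple("A", "B", "D").values()) == 1


class TestStar:
    def test_all_identical_gene_trees(self):
        gt = make_tree("(((A,B),C),(D,E));")
        res = at.STAR([gt.clone(depth=1) for _ in range(10)]).fit()
        assert at.rf_distance(res.tree, gt).rf == 0

    def test_three_taxon_rank_averages_match_hand_computation(self):
        # 60/20/20 split among the three rooted triplets
        trees = ([make_tree("((A,B),C);")] * 6 +
                 [make_tree("((A,C),B);")] * 2 +
                 [make_tree("((B,C),A);")] * 2)
        model = at.STAR(trees, outgroup=None)
        D = model.distance_matrix()
        taxa = model.taxa
        # rank 1 cherry (distance 2), rank 2 root (distance 4)
        expected = {("A", "B"): (6 * 2 + 2 * 4 + 2 * 4) / 10,
                    ("A", "C"): (6 * 4 + 2 * 2 + 2 * 4) / 10,
                    ("B", "C"): (6 * 4 + 2 * 4 + 2 * 2) / 10}
        for (a, b), d in expected.items():
            assert D[taxa.index(a), taxa.index(b)] == pytest.approx(d)
        res = model.fit()
        assert at.rf_distance(res.tree, make_tree("((A,B),C);")).rf == 0

    def test_clean_simulation_recovery(self):
        sp = yule_tree(10, seed=30, min_internal=1.25)
        gts = at.simulate_gene_trees(sp, 100, seed=31)
        res = at.STAR(gts).fit()
        assert res.rf_to(sp).rf == 0

    def test_undefined_pair_rejected(self):
        t1 = make_tree("((A,B),C);")
        t2 = make_tree("((D,E),F);")
        with pytest.raises(ValueError):
            at.STAR([t1, t2]).fit()

    def test_bootstrap_supports_on_result(self):
        sp = yule_tree(8, seed=32, min_internal=1.5)
        gts = at.simulate_gene_trees(sp, 80, seed=33)
        res = at.STAR(gts).fit(bootstrap_replicates=30, seed=1)
        assert 50.0 <= res.mean_bootstrap <= 100.0


class TestMpest:
    def test_triplet_mle_closed_form_value(self):
        # counts (9, 1, 0): t_hat = -ln(1.5 * (1 - 0.9))
        assert at.mpest_triplet_mle(9, 10) == pytest.approx(
            -np.log(0.15), abs=1e-12)

    def test_triplet_mle_matches_numeric_optimum(self):
        for n1, n in [(5, 10), (9, 10), (40, 60), (20, 21), (7, 20)]:
            n2 = (n - n1) // 2
            n3 = n - n1 - n2

            def negll(t):
                p1 = 1 - (2 / 3) * np.exp(-t)
                pa = np.exp(-t) / 3
                return -(n1 * np.log(p1) + (n2 + n3) * np.log(pa))

            res = minimize_scalar(negll, bounds=(1e-6, 10),
                                  method="bounded",
                                  options={"xatol": 1e-10})
            if 1e-6 < res.x < 10 - 1e-3:
                assert at.mpest_triplet_mle(n1, n) == pytest.approx(
                    res.x, abs=1e-6)

    def test_score_zero_in_no_ils_limit(self):
        # all counts matching and t huge: probability ~1 per gene tree
        sp = make_tree("((A:1,B:1):50,C:51);")
        counts = at.triplet_counts([make_tree("((A,B),C);")] * 20)
        assert at.mpest_score(sp, counts) == pytest.approx(0.0, abs=1e-3)

    def test_score_equals_direct_product_on_five_taxon_fixture(self):
        sp = yule_tree(5, seed=40, min_internal=0.8)
        gts = at.simulate_gene_trees(sp, 30, seed=41)
        counts = at.triplet_counts(gts)
        taxa = counts.taxa
        tax_objs = {t.label: t for t in sp.taxon_namespace}
        pdm = sp.phylogenetic_distance_matrix()
        expected = 0.0
        for (a, b, c) in itertools.combinations(taxa, 3):
            tally = counts.for_triple(a, b, c)
            # species-tree resolution and internal branch via node depths
            mrcas = {}
            for x, y in ((a, b), (a, c), (b, c)):
                nd = pdm.mrca(tax_objs[x], tax_objs[y])
                mrcas[(x, y)] = nd.distance_from_root()
            deep_pair = max(mrcas, key=mrcas.get)
            t = mrcas[deep_pair] - min(mrcas.values())
            outsider = ({a, b, c} - set(deep_pair)).pop()
            p1 = 1 - (2 / 3) * np.exp(-t)
            pa = np.exp(-t) / 3
            for taxon, k in tally.items():
                expected += k * np.log(p1 if taxon == outsider else pa)
        assert at.mpest_score(sp, counts) == pytest.approx(expected,
                                                           rel=1e-9)

    def test_negative_branch_rejected(self):
        sp = make_tree("((A:1,B:1):-0.5,C:2);")
        counts = at.triplet_counts([make_tree("((A,B),C);")])
        with pytest.raises(ValueError):
            at.mpest_score(sp, counts)

    def test_true_tree_is_local_optimum(self):
        sp = yule_tree(8, seed=50, min_internal=1.25)
        gts = at.simulate_gene_trees(sp, 200, seed=51)
        res = at.MPEST(gts).fit(n_starts=1, start_tree=sp, seed=0)
        assert res.rf_to(sp).rf == 0

    def test_simulation_recovery_five_taxa(self):
        sp = yule_tree(5, seed=52, min_internal=1.0)
        gts = at.simulate_gene_trees(sp, 200, seed=53)
        res = at.MPEST(gts).fit(n_starts=3, seed=0)
        assert res.rf_to(sp).rf == 0
        assert not res.unresolved
        assert res.log_pseudolikelihood < 0

    def test_uniform_counts_flagged_unresolved(self):
        taxa = ["A", "B", "C", "D"]
        import anchortree.speciestree as stree
        triples = stree._triple_arrays(4)
        counts = at.TripletCounts(
            taxa=taxa, triples=triples,
            counts=np.full((len(triples), 3), 10, dtype=np.int64))
        res = at.MPEST(counts=counts).fit(n_starts=6, seed=0)
        assert res.unresolved

    def test_branch_lengths_recovered_roughly(self):
        sp = make_tree("((A:1,B:1):1.0,C:2.0);")
        gts = at.simulate_gene_trees(sp, 4000, seed=54)
        res = at.MPEST(gts).fit(n_starts=2, seed=0)
        internal = [nd.edge.length
                    for nd in res.tree.preorder_internal_node_iter()
                    if nd is not res.tree.seed_node]
        assert len(internal) == 1
        assert internal[0] == pytest.approx(1.0, abs=0.15)

    def test_deterministic_and_order_invariant(self):
        sp = yule_tree(6, seed=55, min_internal=1.0)
        gts = at.simulate_gene_trees(sp, 50, seed=56)
        r1 = at.MPEST(gts).fit(n_starts=3, seed=9)
        r2 = at.MPEST(list(reversed(gts))).fit(n_starts=3, seed=9)
        assert r1.newick() == r2.newick()
        c1 = at.triplet_counts(gts)
        c2 = at.triplet_counts(list(reversed(gts)))
        assert np.array_equal(c1.counts, c2.counts)


class TestAgreement:
    def test_star_and_mpest_agree_on_clean_data(self):
        sp = yule_tree(10, seed=60, min_internal=1.25)
        gts = at.simulate_gene_trees(sp, 100, seed=61)
        star = at.STAR(gts).fit()
        mpest = at.MPEST(gts).fit(n_starts=2, seed=0)
        assert at.rf_distance(star.tree, mpest.tree).percent == 0.0
        assert star.rf_to(sp).rf == 0


class TestMetatree:
    def test_duplicate_trees_cluster_first(self):
        base = yule_tree(6, seed=70)
        other = yule_tree(6, seed=71)
        labelled = [("t1", base), ("t2", base.clone(depth=1)),
                    ("x", other)]
        meta = at.metatree(labelled)
        leaves = {lf.taxon.label for lf in meta.leaf_node_iter()}
        assert leaves == {"t1", "t2", "x"}
        pdm = meta.phylogenetic_distance_matrix()
        tax = {t.label: t for t in meta.taxon_namespace}
        assert pdm.distance(tax["t1"], tax["t2"]) == pytest.approx(0.0)

    def test_outlier_on_longest_terminal_branch(self):
        base = yule_tree(8, seed=72)
        outlier = yule_tree(8, seed=73)
        labelled = [(f"t{i}", base.clone(depth=1)) for i in range(6)]
        labelled.append(("out", outlier))
        meta = at.metatree(labelled)
        terms = {lf.taxon.label: (lf.edge.length or 0.0)
                 for lf in meta.leaf_node_iter()}
        assert terms["out"] == max(terms.values())

    def test_distances_consistent_with_rf(self):
        trees = [yule_tree(6, seed=s) for s in (80, 81, 82)]
        labelled = [(f"t{i}", t) for i, t in enumerate(trees)]
        meta = at.metatree(labelled)
        pdm = meta.phylogenetic_distance_matrix()
        tax = {t.label: t for t in meta.taxon_namespace}
        for i in range(3):
            for j in range(i + 1, 3):
                rf = at.rf_distance(trees[i], trees[j]).rf
                assert pdm.distance(tax[f"t{i}"], tax[f"t{j}"]) == \
                    pytest.approx(rf, abs=1e-9)

    def test_too_few_trees_rejected(self):
        with pytest.raises(ValueError):
            at.metatree([("a", yule_tree(5, 1)), ("b", yule_tree(5, 2))])
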