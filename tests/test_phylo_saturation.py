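"""Saturation filtering, NJ, parsimony, bootstrap and RF distances."""

import itertools
import math
import random

import dendropy
import numpy as np
import pytest

from egtkit import phylo_saturation as ps
from egtkit.seq_io import ProteinAlignment


@pytest.fixture(scope="module")
def lg():
    return ps.lg_model()


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


class TestSubstitutionModel:
    def test_pair_probabilities_normalised_and_symmetric(self, lg):
        p = lg.pair_prob
        assert np.allclose(p, p.T)
        assert np.allclose(np.diag(p), 0.0)
        iu = np.triu_indices(20, k=1)
        assert p[iu].sum() == pytest.approx(1.0)
        assert p[iu].min() < lg.cutoff < p[iu].max()

    def test_classification_boundaries(self, lg):
        assert ps.classify_pair_saturation("A", "A", lg) == "identical"
        everything = ps.lg_model(cutoff=0.0)
        nothing = ps.lg_model(cutoff=float(lg.pair_prob.max()) * 1.01)
        for r1, r2 in itertools.combinations(ps.AA_ORDER, 2):
            assert ps.classify_pair_saturation(r1, r2, everything) == "frequent"
            assert ps.classify_pair_saturation(r1, r2, nothing) == "rare"

    def test_nonstandard_residue_excluded(self, lg):
        assert ps.classify_pair_saturation("A", "X", lg) == "excluded"


class TestSaturationFilteredDistance:
    def test_identical_rows_zero(self, lg):
        aln = ProteinAlignment(ids=list("abc"), rows=["MKV", "MKV", "MKV"])
        dm = ps.saturation_filtered_distance(aln, lg)
        assert np.allclose(dm.d, 0.0)

    def test_cutoff_zero_equals_plain_poisson_bitwise(self):
        rng = random.Random(8)
        rows = ["".join(rng.choice(ps.AA_ORDER) for _ in range(60)) for _ in range(5)]
        aln = ProteinAlignment(ids=list("abcde"), rows=rows)
        filtered = ps.saturation_filtered_distance(aln, ps.lg_model(cutoff=0.0))
        plain = ps.plain_distance(aln)
        assert (filtered.d == plain.d).all()

    def test_hand_marked_rare_pairs(self):
        # custom model: only the A<->R pair is rare
        pair = np.full((20, 20), 1.0)
        np.fill_diagonal(pair, 0.0)
        ia, ir = ps.AA_INDEX["A"], ps.AA_INDEX["R"]
        pair[ia, ir] = pair[ir, ia] = 0.0
        model = ps.SubstitutionModel(name="toy", pair_prob=pair, cutoff=0.5)
        aln = ProteinAlignment(
            ids=list("wxyz"),
            rows=["AAKKK", "RAKKK", "AGKKK", "AAKKW"],
        )
        dm = ps.saturation_filtered_distance(aln, model, use_mask=False)
        # w-x: column 0 is A/R -> rare, dropped; 4 effective, 0 differ
        assert dm.get("w", "x") == pytest.approx(0.0)
        assert dm.effective_sites[0, 1] == 4
        # w-y: 5 effective, 1 frequent difference -> -ln(1 - 1/5)
        assert dm.get("w", "y") == pytest.approx(-math.log(1 - 1 / 5))
        # x-y: A/R dropped again; differs at column 1 (A/G) -> -ln(1 - 1/4)
        assert dm.get("x", "y") == pytest.approx(-math.log(1 - 1 / 4))

    def test_zero_effective_sites_is_error_naming_pair(self):
        pair = np.zeros((20, 20))
        model = ps.SubstitutionModel(name="toy", pair_prob=pair, cutoff=0.5)
        aln = ProteinAlignment(ids=["a", "b", "c"], rows=["AK", "RW", "AK"])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            ps.saturation_filtered_distance(aln, model, use_mask=False)


def _additive_matrix_from_tree(tree, taxa):
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    d = np.zeros((n, n))
    tax = {t.label: t for t in tree.taxon_namespace}
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.distance(tax[taxa[i]], tax[taxa[j]])
    return ps.DistanceMatrix(taxa=taxa, d=d)


class TestNeighborJoining:
    def test_three_taxa_three_point_formula(self):
        d = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 8.0], [9.0, 8.0, 0.0]])
        tree = ps.neighbor_joining(ps.DistanceMatrix(taxa=list("abc"), d=d))
        # three-point formulas: leaf edges (5+9-8)/2, (5+8-9)/2, (9+8-5)/2
        # sum pairwise to reproduce the input distances exactly
        recovered = _additive_matrix_from_tree(tree, list("abc"))
        assert np.allclose(recovered.d, d, atol=1e-9)

    def test_additive_six_taxon_recovery_exact(self):
        newick = "((a:0.12,b:0.27):0.11,(c:0.31,d:0.09):0.05,(e:0.21,f:0.14):0.18);"
        truth = _tree(newick)
        taxa = list("abcdef")
        dm = _additive_matrix_from_tree(truth, taxa)
        inferred = ps.neighbor_joining(dm)
        assert ps.rf_distance(inferred, truth) == 0
        # branch lengths recovered to numerical precision
        inferred_d = _additive_matrix_from_tree(inferred, taxa)
        assert np.allclose(inferred_d.d, dm.d, atol=1e-9)

    def test_taxon_order_permutation_invariance(self):
        rng = random.Random(17)
        newick = "((a:0.2,b:0.4):0.1,(c:0.3,d:0.1):0.2,(e:0.25,f:0.15):0.1);"
        truth = _tree(newick)
        taxa = list("abcdef")
        dm = _additive_matrix_from_tree(truth, taxa)
        base = ps.tree_splits(ps.neighbor_joining(dm))
        for _ in range(5):
            perm = list(range(6))
            rng.shuffle(perm)
            dm2 = ps.DistanceMatrix(
                taxa=[taxa[i] for i in perm], d=dm.d[np.ix_(perm, perm)]
            )
            assert ps.tree_splits(ps.neighbor_joining(dm2)) == base

    def test_topology_agrees_with_dendropy_nj(self):
        # independent implementation cross-check on random noisy matrices
        import io

        rng = np.random.default_rng(29)
        taxa = [f"t{i}" for i in range(7)]
        for _ in range(5):
            d = rng.random((7, 7)) + 0.5
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            mine = ps.neighbor_joining(ps.DistanceMatrix(taxa=taxa, d=d))
            buf = io.StringIO()
            buf.write("," + ",".join(taxa) + "\n")
            for name, row in zip(taxa, d):
                buf.write(name + "," + ",".join(f"{x:.12g}" for x in row) + "\n")
            buf.seek(0)
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
            theirs = pdm.nj_tree()
            theirs.is_rooted = False
            assert ps.rf_distance(mine, theirs) == 0

    def test_nonfinite_distances_rejected(self):
        d = np.array([[0.0, np.inf, 1.0], [np.inf, 0.0, 1.0], [1.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="finite"):
            ps.neighbor_joining(ps.DistanceMatrix(taxa=list("abc"), d=d))


class TestParsimonyInformative:
    @pytest.mark.parametrize(
        "column,informative", [("AACC", True), ("AAAC", False), ("ARND", False),
                               ("AAC-", False), ("CCAA", True)],
    )
    def test_single_columns(self, column, informative):
        rows = [c for c in column]
        assert ps.parsimony_informative_count(rows) == int(informative)

    def test_toy_matrix_hand_count(self):
        rows = [
            "AAKKWWRRDD",
            "AAKRWARRDE",
            "ACRKWWRADD",
            "ACRRWARADE",
        ]
        # hand enumeration per column:
        # 0:AAAA no; 1:ACAC yes; 2:KKRR yes; 3:KRKR yes; 4:WWWW no;
        # 5:WAWA yes; 6:RRRR no; 7:RRAA yes; 8:DDDD no; 9:DEDE yes
        assert ps.parsimony_informative_count(rows) == 6


def _oracle_fitch(tree_adj, n_leaves, leaf_states):
    """Independent parsimony score: minimise over all internal-state
    assignments drawn from the states present in the column."""
    internals = [n for n in tree_adj if n >= n_leaves]
    states = sorted(set(leaf_states))
    best = None
    edges = [(u, v) for u in tree_adj for v in tree_adj[u] if u < v]
    for assignment in itertools.product(states, repeat=len(internals)):
        state_of = dict(zip(internals, assignment))
        for leaf in range(n_leaves):
            state_of[leaf] = leaf_states[leaf]
        score = sum(state_of[u] != state_of[v] for u, v in edges)
        if best is None or score < best:
            best = score
    return best


class TestFitchScore:
    def test_uniform_alignment_scores_zero(self):
        aln = ProteinAlignment(ids=list("abcd"), rows=["MKV"] * 4)
        tree = _tree("((a,b),(c,d));")
        assert ps.fitch_score(tree, aln) == 0

    def test_four_taxon_column_over_all_topologies(self):
        aln = ProteinAlignment(ids=list("abcd"), rows=["A", "A", "C", "C"])
        scores = {
            "((a,b),(c,d));": 1,
            "((a,c),(b,d));": 2,
            "((a,d),(b,c));": 2,
        }
        for newick, expected in scores.items():
            assert ps.fitch_score(_tree(newick), aln) == expected

    def test_invariant_under_rerooting_and_leaf_order(self):
        rng = random.Random(23)
        rows = ["".join(rng.choice("ARND") for _ in range(15)) for _ in range(6)]
        ids = list("abcdef")
        aln = ProteinAlignment(ids=ids, rows=rows)
        tree = _tree("((a,(b,c)),(d,(e,f)));")
        base = ps.fitch_score(tree, aln)
        rerooted = _tree("(((d,(e,f)),a),(b,c));")
        assert ps.fitch_score(rerooted, aln) == base
        perm = list(range(6))
        rng.shuffle(perm)
        aln2 = ProteinAlignment(ids=[ids[i] for i in perm], rows=[rows[i] for i in perm])
        assert ps.fitch_score(tree, aln2) == base

    def test_matches_state_assignment_oracle(self):
        rng = random.Random(31)
        for _ in range(10):
            n = rng.choice([4, 5, 6])
            rows = ["".join(rng.choice("ARND") for _ in range(6)) for _ in range(n)]
            aln = ProteinAlignment(ids=[f"t{i}" for i in range(n)], rows=rows)
            trees, best_score = ps.mp_search(aln)
            ut, taxa = ps._dendropy_to_utree(trees[0], list(aln.ids))
            oracle = sum(
                _oracle_fitch(ut.adj, ut.n_leaves,
                              [rows[aln.ids.index(t)][j] for t in taxa])
                for j in range(6)
            )
            assert ps.fitch_score(trees[0], aln) == oracle == best_score


class TestMpSearch:
    def test_single_informative_column_fixes_topology(self):
        aln = ProteinAlignment(ids=list("abcd"), rows=["AK", "AK", "CK", "CK"])
        trees, score = ps.mp_search(aln)
        assert score == 1
        assert len(trees) == 1
        assert frozenset("ab") in ps.tree_splits(trees[0]) or frozenset("cd") in ps.tree_splits(trees[0])

    def test_no_informative_columns_all_cooptimal(self):
        aln = ProteinAlignment(ids=list("abcd"), rows=["A", "A", "A", "C"])
        trees, score = ps.mp_search(aln)
        assert score == 1
        assert len(trees) == 3  # every 4-taxon topology

    def test_exhaustive_and_hillclimb_agree_on_seven_taxa(self):
        rng = random.Random(41)
        # 7 taxa with clean clade structure
        clades = {"a": "AAAA", "b": "AAAA", "c": "AACC", "d": "CCCC",
                  "e": "CCCC", "f": "CCGG", "g": "GGGG"}
        noise = {t: "".join(rng.choice("ARNDCQ") for _ in range(10)) for t in clades}
        aln = ProteinAlignment(
            ids=list(clades), rows=[clades[t] + noise[t] for t in clades]
        )
        exhaustive_trees, exhaustive_score = ps.mp_search(aln, exhaustive_limit=8)
        start = ps.neighbor_joining(ps.plain_distance(aln))
        hill_trees, hill_score = ps.mp_search(aln, exhaustive_limit=4, start_tree=start)
        assert hill_score == exhaustive_score


class TestBootstrap:
    def test_fully_consistent_alignment_gets_full_support(self):
        aln = ProteinAlignment(ids=list("abcd"), rows=["AK" * 10, "AK" * 10,
                                                       "CR" * 10, "CR" * 10])
        tree = ps.bootstrap_support(aln, ps.nj_plain_builder, replicates=50, seed=3)
        supports = [
            int(n.label) for n in tree.preorder_internal_node_iter() if n.label
        ]
        assert supports and all(s == 100 for s in supports)

    def test_same_seed_reproducible(self):
        rng = random.Random(19)
        rows = ["".join(rng.choice("ARNDCQEG") for _ in range(40)) for _ in range(5)]
        aln = ProteinAlignment(ids=list("abcde"), rows=rows)
        t1 = ps.bootstrap_support(aln, ps.nj_plain_builder, replicates=30, seed=11)
        t2 = ps.bootstrap_support(aln, ps.nj_plain_builder, replicates=30, seed=11)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_true_splits_better_supported_than_false_on_clean_data(self):
        from egtkit import egt_simulator as sim

        true_support, false_support = [], []
        for seed in range(8):
            cfg = sim.SimulationConfig(
                newick="((a:0.2,b:0.2)ab:0.15,(c:0.2,d:0.2)cd:0.15,(e:0.2,f:0.2)ef:0.15)r;",
                root_cds_length=200,
                at_bias={"plastid": 0.5, "nuclear": 0.5},
                p_nonsyn_accept=0.5,
                seed=seed,
            )
            genes, truth = sim.simulate_egt(cfg)
            aln = sim.genes_to_alignment(genes)
            tree = ps.bootstrap_support(aln, ps.nj_plain_builder, replicates=40, seed=seed)
            truth_splits = ps.tree_splits(truth.tree)
            for node in tree.preorder_internal_node_iter():
                if not node.label:
                    continue
                leaves = {l.taxon.label for l in node.leaf_iter()}
                all_leaves = ps.leaf_labels(tree)
                ref = min(all_leaves)
                side = leaves if ref not in leaves else all_leaves - leaves
                (true_support if frozenset(side) in truth_splits else false_support).append(
                    int(node.label)
                )
        assert true_support
        if false_support:  # clean data may never produce a false split
            assert np.mean(true_support) > np.mean(false_support)


class TestRfDistance:
    def test_identical_trees(self):
        t = _tree("((a,b),(c,d));")
        assert ps.rf_distance(t, t) == 0

    def test_four_taxon_alternatives(self):
        assert ps.rf_distance(_tree("((a,b),(c,d));"), _tree("((a,c),(b,d));")) == 2

    def test_leaf_mismatch_raises(self):
        with pytest.raises(ValueError, match="leaf"):
            ps.rf_distance(_tree("((a,b),(c,d));"), _tree("((a,b),(c,e));"))

    def test_matches_split_set_oracle_on_random_trees(self):
        rng = np.random.default_rng(5)
        taxa = [f"t{i}" for i in range(8)]
        for _ in range(10):
            trees = []
            for _ in range(2):
                d = rng.random((8, 8))
                d = (d + d.T) / 2
                np.fill_diagonal(d, 0.0)
                trees.append(ps.neighbor_joining(ps.DistanceMatrix(taxa=taxa, d=d)))
            oracle = len(ps.tree_splits(trees[0]) ^ ps.tree_splits(trees[1]))
            assert ps.rf_distance(*trees) == oracle
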