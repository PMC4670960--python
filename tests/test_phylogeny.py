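"""Distance corrections, neighbor joining, two-state ML and bootstrap,
with independent oracles: path-sum additive matrices, exhaustive
likelihood enumeration, and scikit-bio's NJ."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrhet.heterogeneity import GeneRegionMatrix
from mrhet.io import RegionLabel
from mrhet.phylogeny import (
    D_MAX,
    CharacterMatrix,
    DistanceMatrix,
    PhyloTree,
    bootstrap_support,
    build_character_matrix,
    cfn_distance,
    log_likelihood,
    ml_optimize,
    neighbor_joining,
    pairwise_distance,
    robinson_foulds,
    root_at_normal,
)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def path_distance(tree: PhyloTree, a: str, b: str) -> float:
    na, nb = tree.node_of(a), tree.node_of(b)
    dist = {na: 0.0}
    stack = [na]
    while stack:
        u = stack.pop()
        for v, length in tree.adjacency[u].items():
            if v not in dist:
                dist[v] = dist[u] + length
                stack.append(v)
    return dist[nb]


def random_binary_tree(taxa, rng) -> PhyloTree:
    """Random unrooted binary tree with positive branch lengths, built by
    sequential leaf attachment (independent of the NJ code path)."""
    adjacency = {}
    leaf_names = {}

    def add_edge(u, v, length):
        adjacency.setdefault(u, {})[v] = length
        adjacency.setdefault(v, {})[u] = length

    nid = itertools.count()
    a, b, c, center = next(nid), next(nid), next(nid), next(nid)
    for leaf, name in zip((a, b, c), taxa[:3]):
        leaf_names[leaf] = name
        add_edge(leaf, center, float(rng.uniform(0.5, 2.0)))
    for name in taxa[3:]:
        edges = [(u, v) for u in adjacency for v in adjacency[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        length = adjacency[u][v]
        mid, leaf = next(nid), next(nid)
        del adjacency[u][v], adjacency[v][u]
        split = float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, length * split)
        add_edge(mid, v, length * (1 - split))
        add_edge(mid, leaf, float(rng.uniform(0.5, 2.0)))
        leaf_names[leaf] = name
    return PhyloTree(adjacency=adjacency, leaf_names=leaf_names)


def additive_matrix(tree: PhyloTree) -> DistanceMatrix:
    taxa = tree.taxa
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = path_distance(tree, taxa[i], taxa[j])
    return DistanceMatrix(taxa=list(taxa), d=d)


def exhaustive_log_likelihood(tree: PhyloTree, c: CharacterMatrix) -> float:
    """Independent oracle: sum over every assignment of states to internal
    nodes, joint probability from explicit edge transition products."""
    internals = sorted(n for n in tree.adjacency if n not in tree.leaf_names)
    row_of = {name: i for i, name in enumerate(c.taxa)}
    edges = tree.edges()
    total = 0.0
    for site in range(c.n_sites):
        leaf_state = {
            node: int(c.data[row_of[name], site])
            for node, name in tree.leaf_names.items()
        }
        site_prob = 0.0
        for assignment in itertools.product((0, 1), repeat=len(internals)):
            states = dict(zip(internals, assignment))
            states.update(leaf_state)
            prob = 0.5  # stationary probability at an arbitrary reference node
            for u, v, length in edges:
                e = math.exp(-2.0 * length)
                same = (1 + e) / 2
                prob *= same if states[u] == states[v] else (1 - same)
            site_prob += prob
        total += math.log(site_prob)
    return total


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


class TestDistances:
    def test_identical_rows_zero_under_both_models(self):
        data = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 1]], bool)
        cm = CharacterMatrix(["A", "B", "C"], data, ["s1", "s2", "s3"])
        for model in ("p_distance", "cfn"):
            dm = pairwise_distance(cm, model=model)
            assert dm.d[0, 1] == 0.0

    def test_cfn_closed_form(self):
        assert cfn_distance(0.1) == pytest.approx(-0.5 * math.log(0.8))
        assert cfn_distance(0.1) == pytest.approx(0.11157, abs=1e-5)

    def test_saturated_p_capped(self):
        assert cfn_distance(0.6) == D_MAX
        data = np.array([[1] * 10, [0] * 10], bool)
        cm = CharacterMatrix(["A", "B"], data, [f"s{i}" for i in range(10)])
        assert pairwise_distance(cm, "cfn").d[0, 1] == D_MAX

    def test_zero_sites_rejected(self):
        cm = CharacterMatrix(["A", "B"], np.zeros((2, 0), bool), [])
        with pytest.raises(ValueError):
            pairwise_distance(cm)

    def test_p_distance_is_mismatch_fraction(self):
        data = np.array([[1, 0, 1, 0], [1, 1, 0, 0]], bool)
        cm = CharacterMatrix(["A", "B"], data, list("abcd"))
        assert pairwise_distance(cm, "p_distance").d[0, 1] == 0.5


class TestCharacterMatrix:
    def test_normal_appended_all_absent(self, regions4):
        present = np.ones((5, 4), bool)
        m = GeneRegionMatrix([f"G{i}" for i in range(5)], regions4, present)
        cm = build_character_matrix(m, include_normal=True)
        assert cm.taxa[-1] == "N" and cm.normal == "N"
        assert not cm.data[-1].any()
        assert cm.data.shape == (5, 5)

    def test_normal_row_must_be_absent(self):
        with pytest.raises(ValueError, match="all-absent"):
            CharacterMatrix(["A", "N"], np.ones((2, 2), bool), ["s1", "s2"], normal="N")

    def test_too_few_regions_rejected(self, regions4):
        m = GeneRegionMatrix(["G0"], regions4[:1], np.ones((1, 1), bool))
        with pytest.raises(ValueError):
            build_character_matrix(m)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_recovers_known_four_taxon_tree_exactly(self):
        # ((A:1,B:2):1,(C:3,D:1)) -> six path-sum distances, NJ must return
        # the same topology and branch lengths
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        expected = frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        assert set(tree.bipartitions()) == {expected}
        for a, b in itertools.combinations(taxa, 2):
            assert path_distance(tree, a, b) == pytest.approx(d[taxa.index(a), taxa.index(b)])

    def test_three_taxa_three_point_formulas(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        # a = (dAB + dAC - dBC)/2 = 1, b = 2, c = 3
        center = next(n for n in tree.adjacency if n not in tree.leaf_names)
        lengths = {tree.leaf_names[leaf]: tree.adjacency[center][leaf]
                   for leaf in tree.leaf_names}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_tie_break_is_deterministic(self):
        # four equidistant taxa: every Q is tied; the smallest index pair wins
        d = np.ones((4, 4)) - np.eye(4)
        trees = [
            neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], d.copy())).to_newick()
            for _ in range(3)
        ]
        assert len(set(trees)) == 1
        expected = frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], d))
        assert set(tree.bipartitions()) == {expected}

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    @given(st.integers(4, 8), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_exact_on_random_additive_matrices(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"L{i}" for i in range(n_taxa)]
        true_tree = random_binary_tree(taxa, rng)
        dm = additive_matrix(true_tree)
        inferred = neighbor_joining(dm)
        assert robinson_foulds(inferred, true_tree) == 0
        for a, b in itertools.combinations(taxa, 2):
            assert path_distance(inferred, a, b) == pytest.approx(
                path_distance(true_tree, a, b), abs=1e-9
            )

    def test_matches_scikit_bio_on_random_characters(self, rng):
        skbio_nj = pytest.importorskip("skbio.tree").nj
        from skbio import DistanceMatrix as SkbioDM

        data = rng.random((6, 40)) < 0.4
        cm = CharacterMatrix([f"L{i}" for i in range(6)], data,
                             [f"s{i}" for i in range(40)])
        dm = pairwise_distance(cm, "p_distance")
        ours = neighbor_joining(dm)
        theirs = skbio_nj(SkbioDM(dm.d, ids=dm.taxa))
        their_bips = set()
        for node in theirs.non_tips():
            names = frozenset(t.name for t in node.tips())
            if 2 <= len(names) <= len(dm.taxa) - 2:
                their_bips.add(
                    frozenset({names, frozenset(dm.taxa) - names})
                )
        assert set(ours.bipartitions()) == their_bips


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------


class TestLikelihood:
    @given(st.integers(4, 6), st.integers(1, 8), st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_pruning_equals_exhaustive_enumeration(self, n_taxa, n_sites, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"L{i}" for i in range(n_taxa)]
        tree = random_binary_tree(taxa, rng)
        data = rng.random((n_taxa, n_sites)) < 0.5
        cm = CharacterMatrix(taxa, data, [f"s{i}" for i in range(n_sites)])
        assert log_likelihood(tree, cm) == pytest.approx(
            exhaustive_log_likelihood(tree, cm), rel=1e-9
        )

    def test_constant_site_at_zero_lengths_is_half(self):
        taxa = ["A", "B", "C"]
        adjacency = {0: {3: 0.0}, 1: {3: 0.0}, 2: {3: 0.0},
                     3: {0: 0.0, 1: 0.0, 2: 0.0}}
        tree = PhyloTree(adjacency, {0: "A", 1: "B", 2: "C"})
        cm = CharacterMatrix(taxa, np.ones((3, 1), bool), ["s"])
        assert log_likelihood(tree, cm) == pytest.approx(math.log(0.5))

    def test_optimization_never_decreases_likelihood(self, rng):
        taxa = [f"L{i}" for i in range(5)]
        tree = random_binary_tree(taxa, rng)
        data = rng.random((5, 30)) < 0.5
        cm = CharacterMatrix(taxa, data, [f"s{i}" for i in range(30)])
        before = log_likelihood(tree, cm)
        optimized, after = ml_optimize(tree, cm, search="lengths_only")
        assert after >= before - 1e-9
        assert log_likelihood(optimized, cm) == pytest.approx(after)

    def test_nni_search_finds_better_topology(self, rng):
        # characters generated cleanly on a known topology; start NJ from a
        # deliberately wrong tree and let NNI repair it
        taxa = ["A", "B", "C", "D"]
        data = np.array(
            [[1] * 20 + [0] * 40, [1] * 20 + [0] * 40,
             [0] * 20 + [1] * 20 + [0] * 20, [0] * 40 + [1] * 20]
        ).astype(bool)
        cm = CharacterMatrix(taxa, data, [f"s{i}" for i in range(60)])
        wrong = PhyloTree.from_newick("((A:0.1,C:0.1):0.1,(B:0.1,D:0.1):0.1);")
        fixed, ll_fixed = ml_optimize(wrong, cm, search="nni")
        _, ll_wrong = ml_optimize(wrong, cm, search="lengths_only")
        assert ll_fixed > ll_wrong
        expected = frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        assert set(fixed.bipartitions()) == {expected}

    def test_zero_sites_rejected(self, rng):
        taxa = ["A", "B", "C"]
        tree = random_binary_tree(taxa, rng)
        cm = CharacterMatrix(taxa, np.zeros((3, 0), bool), [])
        with pytest.raises(ValueError):
            log_likelihood(tree, cm)


# ---------------------------------------------------------------------------
# bootstrap and rooting
# ---------------------------------------------------------------------------


from mrhet.simulate import compatible_character_matrix as clean_clustered_matrix


class TestBootstrap:
    def test_clean_splits_get_full_support(self):
        cm = clean_clustered_matrix()
        tree = bootstrap_support(cm, n=200, seed=5)
        assert tree.supports  # at least one internal edge
        assert all(s == 100.0 for s in tree.supports.values())

    def test_same_seed_reproducible(self):
        cm = clean_clustered_matrix(5)
        a = bootstrap_support(cm, n=30, seed=11)
        b = bootstrap_support(cm, n=30, seed=11)
        assert a.supports == b.supports

    def test_single_replicate_supports_are_binary(self, rng):
        data = rng.random((5, 40)) < 0.5
        cm = CharacterMatrix([f"L{i}" for i in range(5)], data,
                             [f"s{i}" for i in range(40)])
        tree = bootstrap_support(cm, n=1, seed=3)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_taxon_order_permutation_invariance(self):
        cm = clean_clustered_matrix(10)
        perm = [3, 0, 4, 1, 2]
        cm_perm = CharacterMatrix(
            [cm.taxa[i] for i in perm], cm.data[perm], list(cm.site_ids), normal="N"
        )
        a = bootstrap_support(cm, n=50, seed=2)
        b = bootstrap_support(cm_perm, n=50, seed=2)
        assert a.supports == b.supports

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(clean_clustered_matrix(2), n=0, seed=0)


class TestRooting:
    def test_root_degree_two_on_normal_edge(self):
        cm = clean_clustered_matrix(5)
        tree = neighbor_joining(pairwise_distance(cm))
        rooted = root_at_normal(tree, "N")
        assert rooted.root is not None
        assert rooted.degree(rooted.root) == 2
        assert "N" in {
            rooted.leaf_names.get(n) for n in rooted.adjacency[rooted.root]
        }

    def test_root_then_unroot_preserves_bipartitions(self):
        cm = clean_clustered_matrix(5)
        tree = neighbor_joining(pairwise_distance(cm))
        rooted = root_at_normal(tree, "N")
        assert set(rooted.unroot().bipartitions()) == set(tree.bipartitions())

    def test_supports_preserved_across_rooting(self):
        cm = clean_clustered_matrix(5)
        tree = bootstrap_support(cm, n=20, seed=9)
        rooted = root_at_normal(tree, "N")
        assert rooted.supports == tree.supports

    def test_missing_normal_rejected(self):
        cm = clean_clustered_matrix(2)
        tree = neighbor_joining(pairwise_distance(cm))
        with pytest.raises(KeyError):
            root_at_normal(tree, "missing")

    @pytest.mark.parametrize("seed", [3, 7, 21])
    def test_metastasis_nested_within_tumor_clade(self, seed):
        from mrhet.simulate import SimConfig, simulate

        result = simulate(SimConfig(seed=seed, has_metastasis=True))
        cm = build_character_matrix(result.observed)
        rooted = root_at_normal(neighbor_joining(pairwise_distance(cm)), "N")
        sides = [side for b in rooted.unroot().bipartitions() for side in b]
        # M never pairs with the normal...
        assert frozenset({"M", "N"}) not in sides
        # ...and some proper tumor subclade (excluding N) contains it
        assert any("M" in side and "N" not in side for side in sides)


class TestRobinsonFoulds:
    @given(st.integers(4, 7), st.integers(0, 2**31 - 1), st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_dendropy_symmetric_difference(self, n_taxa, seed_a, seed_b):
        import dendropy
        from dendropy.calculate import treecompare

        taxa = [f"L{i}" for i in range(n_taxa)]
        tree_a = random_binary_tree(taxa, np.random.default_rng(seed_a))
        tree_b = random_binary_tree(taxa, np.random.default_rng(seed_b))
        tns = dendropy.TaxonNamespace()
        da = dendropy.Tree.get(
            data=tree_a.to_newick(), schema="newick", taxon_namespace=tns
        )
        db = dendropy.Tree.get(
            data=tree_b.to_newick(), schema="newick", taxon_namespace=tns
        )
        da.encode_bipartitions()
        db.encode_bipartitions()
        assert robinson_foulds(tree_a, tree_b) == treecompare.symmetric_difference(da, db)


class TestVariantLevelCharacters:
    def test_site_count_at_least_gene_level(self, regions4):
        from mrhet.heterogeneity import NON_SILENT, build_gene_matrix
        from mrhet.io import VariantCall
        from mrhet.phylogeny import variant_character_matrix

        t1, t2 = regions4[:2]
        variants = [
            VariantCall(t1, "chr1", 10, "A", "G", "G1", "stopgain"),
            VariantCall(t1, "chr1", 99, "C", "T", "G1", "nonsynonymous SNV"),
            VariantCall(t2, "chr2", 5, "G", "T", "G2", "splicing"),
        ]
        gene_cm = build_character_matrix(
            build_gene_matrix(variants, regions4, NON_SILENT)
        )
        var_cm = variant_character_matrix(variants, regions4, NON_SILENT)
        assert var_cm.n_sites >= gene_cm.n_sites
        assert var_cm.n_sites == 3 and gene_cm.n_sites == 2
        assert not var_cm.data[-1].any()  # normal row all-absent
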