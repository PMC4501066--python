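"""WLS tree fitting, tip trimming, and tree comparison metrics."""

import itertools
import math

import numpy as np
import pytest

from aafphylo.distance import DistanceMatrix
from aafphylo.tree import (
    PhyloTree,
    branch_score_distance,
    fit_tree,
    topological_mistakes,
    trim_tips,
    wls_objective,
)


def matrix_from_tree(nwk: str, n_t: int = 100_000, k: int = 21) -> tuple[PhyloTree, DistanceMatrix]:
    t = PhyloTree.from_newick(nwk)
    D = t.patristic_matrix()
    n = t.n_taxa
    NT = np.full((n, n), n_t, dtype=np.int64)
    NS = (NT * np.exp(-k * D)).astype(np.int64)
    return t, DistanceMatrix(t.taxa, D, NS, NT, k)


FIVE_TAXON = "((A:0.02,B:0.03):0.012,(C:0.04,D:0.015):0.02,E:0.05);"


def random_tree_newick(rng, n: int, scale: float = 0.05) -> str:
    """Random binary topology with exponential branch lengths."""
    import dendropy

    taxa = [f"t{i:02d}" for i in range(n)]
    ns = dendropy.TaxonNamespace(taxa)
    t = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=ns,
        num_extant_tips=n, rng=__import__("random").Random(int(rng.integers(1 << 30))),
    )
    t.deroot()  # basal trifurcation: unrooted reading is unambiguous
    for e in t.edges():
        if e.length is not None:
            e.length = float(rng.exponential(scale)) + 1e-4
    t.seed_node.edge.length = None  # no root edge on an unrooted tree
    return t.as_string(schema="newick", suppress_rooting=True)


class TestNewickRoundtrip:
    def test_patristic_preserved(self):
        t = PhyloTree.from_newick(FIVE_TAXON)
        t2 = PhyloTree.from_newick(t.to_newick())
        assert t2.taxa == t.taxa
        assert np.allclose(t.patristic_matrix(), t2.patristic_matrix(), atol=1e-9)

    def test_rooted_bifurcation_suppressed(self):
        rooted = "((A:0.1,B:0.2):0.05,C:0.3);"
        t = PhyloTree.from_newick(rooted)
        # unrooted 3-taxon star: 3 edges
        assert len(t.edges) == 3


class TestFitTree:
    def test_exact_additive_recovery(self):
        true, M = matrix_from_tree(FIVE_TAXON)
        fitted = fit_tree(M)
        assert topological_mistakes(fitted, true) == 0
        assert branch_score_distance(fitted, true) < 1e-6
        assert wls_objective(fitted, M) < 1e-10

    def test_matches_exhaustive_topology_search(self, rng):
        """The NNI optimum equals brute force over all 15 unrooted 5-taxon
        topologies on noisy matrices."""
        from aafphylo.tree import _weighted_nnls_lengths

        taxa = list("ABCDE")
        topologies = []
        # all 15 unrooted binary topologies on 5 taxa: choose the cherry pair
        # and the taxon attached to the middle
        for pair in itertools.combinations(range(5), 2):
            rest = [i for i in range(5) if i not in pair]
            for mid in rest:
                o = [i for i in rest if i != mid]
                nwk = (
                    f"(({taxa[pair[0]]}:1,{taxa[pair[1]]}:1):1,"
                    f"{taxa[mid]}:1,({taxa[o[0]]}:1,{taxa[o[1]]}:1):1);"
                )
                topologies.append(PhyloTree.from_newick(nwk))
        assert len({frozenset(t.bipartitions(internal_only=True)) for t in topologies}) == 15

        for trial in range(5):
            true, M = matrix_from_tree(FIVE_TAXON, n_t=3000)
            noisy = M.D + rng.normal(0, 0.004, M.D.shape)
            noisy = np.triu(noisy, 1)
            noisy = np.maximum(noisy + noisy.T, 0.001)
            np.fill_diagonal(noisy, 0)
            Mn = DistanceMatrix(M.taxa, noisy, M.n_s, M.n_t, M.k)
            fitted = fit_tree(Mn)
            best_obj = math.inf
            d = Mn.condensed()
            n_t = Mn.condensed_nt().astype(float)
            for topo in topologies:
                A = topo.design_matrix()
                _, obj = _weighted_nnls_lengths(A, d, n_t, Mn.k)
                best_obj = min(best_obj, obj)
            assert wls_objective(fitted, Mn) <= best_obj * (1 + 1e-6)

    def test_input_order_invariance(self, rng):
        true, M = matrix_from_tree(
            "((A:0.03,B:0.02):0.01,((C:0.04,D:0.03):0.015,E:0.06):0.01,F:0.05);"
        )
        ref = fit_tree(M)
        for _ in range(5):
            perm = rng.permutation(M.n_taxa)
            Mp = DistanceMatrix(
                [M.taxa[i] for i in perm],
                M.D[np.ix_(perm, perm)],
                M.n_s[np.ix_(perm, perm)],
                M.n_t[np.ix_(perm, perm)],
                M.k,
            )
            fp = fit_tree(Mp)
            assert topological_mistakes(fp, ref) == 0
            assert branch_score_distance(fp, ref) < 1e-6

    def test_three_taxa_star(self):
        D = np.array([[0, 0.2, 0.3], [0.2, 0, 0.25], [0.3, 0.25, 0]])
        NT = np.full((3, 3), 1000)
        M = DistanceMatrix(["a", "b", "c"], D, NT, NT, 13)
        t = fit_tree(M)
        assert len(t.edges) == 3
        assert np.allclose(t.patristic_matrix(), D, atol=1e-8)

    def test_nonfinite_rejected(self):
        D = np.full((4, 4), np.nan)
        NT = np.full((4, 4), 10)
        with pytest.raises(ValueError, match="non-finite"):
            fit_tree(DistanceMatrix(list("abcd"), D, NT, NT, 13))

    def test_nonnegative_lengths(self, rng):
        _, M = matrix_from_tree(FIVE_TAXON, n_t=500)
        noisy = np.abs(M.D + rng.normal(0, 0.01, M.D.shape))
        noisy = np.triu(noisy, 1)
        noisy = noisy + noisy.T
        t = fit_tree(DistanceMatrix(M.taxa, noisy, M.n_s, M.n_t, M.k))
        assert np.all(t.lengths >= 0)


class TestObjective:
    def test_zero_for_perfect_tree(self):
        true, M = matrix_from_tree(FIVE_TAXON)
        assert wls_objective(true, M) < 1e-18

    def test_objective_le_nj_start(self, rng):
        from aafphylo.tree import _nj_topology, _weighted_nnls_lengths

        _, M = matrix_from_tree(FIVE_TAXON, n_t=2000)
        noisy = np.triu(M.D + rng.normal(0, 0.006, M.D.shape), 1)
        noisy = np.maximum(noisy + noisy.T, 1e-4)
        np.fill_diagonal(noisy, 0)
        Mn = DistanceMatrix(M.taxa, noisy, M.n_s, M.n_t, M.k)
        nj = _nj_topology(Mn)
        _, nj_obj = _weighted_nnls_lengths(
            nj.design_matrix(), Mn.condensed(), Mn.condensed_nt().astype(float), Mn.k
        )
        assert wls_objective(fit_tree(Mn), Mn) <= nj_obj * (1 + 1e-9)


class TestTrimTips:
    def test_zero_corrections_identity(self):
        t = PhyloTree.from_newick(FIVE_TAXON)
        t2 = trim_tips(t, {x: 0.0 for x in t.taxa})
        assert np.allclose(t.lengths, t2.lengths)

    def test_floor_with_warning(self):
        t = PhyloTree.from_newick(FIVE_TAXON)
        with pytest.warns(UserWarning, match="floored"):
            t2 = trim_tips(t, {"A": 1.0})
        bips = t2.bipartitions()
        mask_a = 1 << t2.taxa.index("A")
        full = (1 << t2.n_taxa) - 1
        key = mask_a if not (mask_a & 1) else full & ~mask_a
        assert bips[key] == 0.0
        # internal branches untouched
        assert topological_mistakes(t, t2) == 0

    def test_unknown_taxon(self):
        t = PhyloTree.from_newick(FIVE_TAXON)
        with pytest.raises(ValueError):
            trim_tips(t, {"Z": 0.01})


class TestTreeComparison:
    def test_identical_trees(self):
        t = PhyloTree.from_newick(FIVE_TAXON)
        assert branch_score_distance(t, t) == 0.0
        assert topological_mistakes(t, t) == 0

    def test_single_edge_difference(self):
        t1 = PhyloTree.from_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.0);")
        t2 = PhyloTree.from_newick("((A:0.1,B:0.1):0.08,(C:0.1,D:0.1):0.0);")
        assert branch_score_distance(t1, t2) == pytest.approx(0.03)
        assert branch_score_distance(t1, t2, sqrt=False) == pytest.approx(0.03**2)

    def test_alternative_quartet_resolution(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):0);")
        t2 = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):0);")
        assert topological_mistakes(t1, t2) == 1

    def test_metric_properties_and_dendropy_oracle(self, rng):
        """BSD is symmetric, zero iff same tree, and matches dendropy's
        Kuhner-Felsenstein branch-length distance on random tree pairs."""
        import dendropy
        from dendropy.calculate import treecompare

        for _ in range(12):
            n = int(rng.integers(5, 9))
            nwk1 = random_tree_newick(rng, n)
            nwk2 = random_tree_newick(rng, n)
            t1 = PhyloTree.from_newick(nwk1)
            t2 = PhyloTree.from_newick(nwk2)
            bsd = branch_score_distance(t1, t2)
            assert bsd == pytest.approx(branch_score_distance(t2, t1))
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            assert bsd == pytest.approx(treecompare.euclidean_distance(d1, d2), rel=1e-9)
            rf = treecompare.symmetric_difference(d1, d2)
            assert topological_mistakes(t1, t2) + topological_mistakes(t2, t1) == rf

    def test_taxon_mismatch(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):0);")
        t2 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,E:1):0);")
        with pytest.raises(ValueError):
            branch_score_distance(t1, t2)
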