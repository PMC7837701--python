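import numpy as np
import pandas as pd
import pytest

from scatlas import (
    cluster_profiles,
    consensus_tree,
    linkage_tree,
    multiscale_bootstrap_support,
    read_newick,
    resampled_builds,
    write_newick,
)
from scatlas.embed import ClusterAssignment
from scatlas.trees import DEFAULT_SCALES, SupportTree, TreeNode, _fit_au


def _pair_tree(pairs, heights=(0.5, 0.5, 1.0)):
    leaves = {l: TreeNode(0.0, name=l) for p in pairs for l in p}
    l = TreeNode(heights[0], children=[leaves[pairs[0][0]], leaves[pairs[0][1]]])
    r = TreeNode(heights[1], children=[leaves[pairs[1][0]], leaves[pairs[1][1]]])
    return SupportTree(TreeNode(heights[2], children=[l, r]))


class TestClusterProfiles:
    def test_centroid_equals_brute_force_mean(self, small_nm):
        labels = np.arange(small_nm.n_cells) % 3
        assign = ClusterAssignment(cells=small_nm.cells, labels=labels,
                                   resolution=0.8)
        prof = cluster_profiles(small_nm, assign)
        for c in range(3):
            ref = small_nm.scaled[:, labels == c].mean(axis=1)
            assert np.allclose(prof.loc[str(c)].to_numpy(), ref)

    def test_one_cell_cluster_is_that_cell(self, small_nm):
        labels = np.zeros(small_nm.n_cells, int)
        labels[0] = 1
        assign = ClusterAssignment(cells=small_nm.cells, labels=labels,
                                   resolution=0.8)
        prof = cluster_profiles(small_nm, assign)
        assert np.allclose(prof.loc["1"].to_numpy(), small_nm.scaled[:, 0])

    def test_duplicated_cells_leave_centroid_unchanged(self, rng):
        from scatlas.preprocess import NormalizedMatrix
        import scipy.sparse as sp

        x = rng.normal(size=(10, 6))
        xdup = np.concatenate([x, x[:, :3]], axis=1)
        def nm_of(arr):
            g, n = arr.shape
            return NormalizedMatrix(
                values=sp.csr_matrix(np.abs(arr)),
                genes=[f"g{i}" for i in range(g)],
                cells=[f"b{i}" for i in range(n)],
                hvg_mask=np.ones(g, bool), scaled=arr)
        a1 = ClusterAssignment(cells=[f"b{i}" for i in range(6)],
                               labels=[0, 0, 0, 1, 1, 1], resolution=1)
        a2 = ClusterAssignment(cells=[f"b{i}" for i in range(9)],
                               labels=[0, 0, 0, 1, 1, 1, 0, 0, 0], resolution=1)
        p1 = cluster_profiles(nm_of(x), a1)
        p2 = cluster_profiles(nm_of(xdup), a2)
        assert np.allclose(p1.loc["0"], p2.loc["0"])


class TestLinkageTree:
    def test_forced_topology(self, rng):
        base = rng.normal(size=40)
        prof = pd.DataFrame(
            [base, base + 0.05 * rng.normal(size=40), rng.normal(size=40)],
            index=["A", "B", "C"])
        t = linkage_tree(prof)
        assert frozenset({"A", "B"}) in t.clades()

    def test_identical_profiles_merge_at_zero_height(self, rng):
        row = rng.normal(size=30)
        t = linkage_tree(pd.DataFrame([row, row, rng.normal(size=30)],
                                      index=["A", "B", "C"]))
        ab = [n for n in t.internal_nodes()
              if sorted(n.leaf_names()) == ["A", "B"]]
        assert ab and ab[0].height == pytest.approx(0.0, abs=1e-12)

    def test_input_order_invariance(self, rng):
        prof = pd.DataFrame(rng.normal(size=(5, 25)),
                            index=["E", "A", "C", "B", "D"])
        t1 = linkage_tree(prof)
        t2 = linkage_tree(prof.iloc[::-1])
        assert t1.clades() == t2.clades()

    def test_constant_profile_warns(self, rng):
        prof = pd.DataFrame([np.ones(10), rng.normal(size=10),
                             rng.normal(size=10)], index=["K", "A", "B"])
        with pytest.warns(UserWarning, match="constant"):
            t = linkage_tree(prof)
        assert set(t.leaves()) == {"K", "A", "B"}

    def test_matches_scipy_tree_structure(self, rng):
        from scipy.cluster.hierarchy import linkage, to_tree
        from scipy.spatial.distance import pdist

        prof = pd.DataFrame(rng.normal(size=(6, 30)),
                            index=[f"L{i}" for i in range(6)])
        mine = linkage_tree(prof, metric="euclidean")
        z = linkage(pdist(prof.to_numpy()), method="average")
        ref = to_tree(z)
        def clades(node, names):
            out = set()
            def rec(n):
                if n.is_leaf():
                    return {names[n.id]}
                s = rec(n.left) | rec(n.right)
                out.add(frozenset(s))
                return s
            rec(node)
            out.discard(frozenset(names))
            return out
        assert mine.clades() == clades(ref, list(prof.index))


class TestConsensus:
    def test_identical_trees_full_support(self):
        t = _pair_tree([("A", "B"), ("C", "D")])
        cons = consensus_tree([t] * 100)
        sup = [n.support for n in cons.internal_nodes() if n.support is not None]
        assert sup and all(s == 100 for s in sup)
        assert cons.clades() == t.clades()

    def test_sixty_forty_split_supports(self):
        t1 = _pair_tree([("A", "B"), ("C", "D")])
        t2 = _pair_tree([("A", "C"), ("B", "D")])
        cons = consensus_tree([t1] * 60 + [t2] * 40)
        ab = {frozenset(n.leaf_names()): n.support
              for n in cons.internal_nodes() if n.support is not None}
        assert ab[frozenset({"A", "B"})] == 60
        assert ab[frozenset({"C", "D"})] == 60
        assert frozenset({"A", "C"}) not in ab

    def test_matches_dendropy_majority_consensus(self):
        dendropy = pytest.importorskip("dendropy")
        t1 = _pair_tree([("A", "B"), ("C", "D")])
        t2 = _pair_tree([("A", "C"), ("B", "D")])
        trees = [t1] * 7 + [t2] * 3
        mine = consensus_tree(trees)
        tl = dendropy.TreeList([dendropy.Tree.get(data=t.newick(), schema="newick")
                                for t in trees])
        ref = tl.consensus(min_freq=0.5)
        all_leaves = frozenset("ABCD")

        def biparts(clades):
            return {frozenset({c, all_leaves - c}) for c in clades}

        ref_clades = set()
        for node in ref.preorder_node_iter():
            names = frozenset(l.taxon.label for l in node.leaf_iter())
            if 1 < len(names) < 4:
                ref_clades.add(names)
        # dendropy consensus is unrooted: compare as bipartitions
        assert biparts(mine.clades()) == biparts(ref_clades)

    def test_inconsistent_leaves_restricted_with_warning(self):
        t1 = _pair_tree([("A", "B"), ("C", "D")])
        t3 = SupportTree(TreeNode(1.0, children=[
            TreeNode(0.0, name="A"),
            TreeNode(0.5, children=[TreeNode(0.0, name="B"),
                                    TreeNode(0.0, name="C")])]))
        with pytest.warns(UserWarning, match="common leaves"):
            cons = consensus_tree([t1, t1, t3])
        assert set(cons.leaves()) == {"A", "B", "C"}

    def test_no_trees_rejected(self):
        with pytest.raises(ValueError):
            consensus_tree([])


class TestMultiscaleBootstrap:
    def test_flat_half_bp_maps_to_au_fifty(self):
        au = _fit_au({float(r): 0.5 for r in DEFAULT_SCALES}, 100)
        assert au == pytest.approx(0.5, abs=0.05)

    def test_zero_curvature_closed_form(self):
        from scipy.stats import norm

        for d in (0.4, 1.1, -0.7):
            bp = {float(r): float(norm.sf(d / np.sqrt(r))) for r in DEFAULT_SCALES}
            assert _fit_au(bp, 200) == pytest.approx(norm.sf(d), abs=1e-3)

    def test_class_defining_edges_get_high_support(self, small_nm, small_sim):
        # leaves are the 8 planted types; the 4 same-class type pairs are
        # held together by 20 shared class markers and must be near-certain
        _, truth = small_sim
        codes, uniq = pd.factorize(truth.table.type_label)
        assign = ClusterAssignment(cells=small_nm.cells, labels=codes,
                                   resolution=0.8)
        tree = multiscale_bootstrap_support(small_nm, assign, n_boot=30, seed=0)
        cmap = {frozenset(n.leaf_names()): n.support
                for n in tree.internal_nodes() if n.support is not None}
        name_of = {t: str(i) for i, t in enumerate(uniq)}
        for cls in ("C0", "C1", "C2", "C3"):
            pair = frozenset({name_of[f"{cls}.t0"], name_of[f"{cls}.t1"]})
            assert pair in cmap and cmap[pair] >= 95

    def test_cell_resampling_unit_runs(self, small_nm, small_sim):
        _, truth = small_sim
        codes, _ = pd.factorize(truth.table.class_label)
        assign = ClusterAssignment(cells=small_nm.cells, labels=codes,
                                   resolution=0.8)
        tree = multiscale_bootstrap_support(small_nm, assign, n_boot=10,
                                            seed=0, unit="cells")
        assert set(tree.leaves()) == {str(c) for c in np.unique(codes)}


class TestResampledBuilds:
    def test_same_seed_identical(self, small_nm, small_sim):
        _, truth = small_sim
        codes, _ = pd.factorize(truth.table.class_label)
        assign = ClusterAssignment(cells=small_nm.cells, labels=codes,
                                   resolution=0.8)
        t1 = resampled_builds(small_nm, assign, n_builds=3, seed=4)
        t2 = resampled_builds(small_nm, assign, n_builds=3, seed=4)
        assert [t.newick() for t in t1] == [t.newick() for t in t2]

    def test_full_fractions_reproduce_full_tree(self, small_nm, small_sim):
        _, truth = small_sim
        codes, _ = pd.factorize(truth.table.class_label)
        assign = ClusterAssignment(cells=small_nm.cells, labels=codes,
                                   resolution=0.8)
        full = linkage_tree(cluster_profiles(small_nm, assign))
        builds = resampled_builds(small_nm, assign, n_builds=2,
                                  cell_frac=1.0, gene_frac=1.0, seed=0)
        assert all(t.clades() == full.clades() for t in builds)


class TestNewick:
    def test_round_trip_with_supports(self):
        t = _pair_tree([("A", "B"), ("C", "D")])
        for n in t.internal_nodes():
            if n is not t.root:
                n.support = 90.0
        s = t.newick()
        back = read_newick(s)
        assert back.clades() == t.clades()
        assert sorted(n.support for n in back.internal_nodes()
                      if n.support is not None) == [90.0, 90.0]

    def test_polytomy_serialized_legally(self, tmp_path):
        dendropy = pytest.importorskip("dendropy")
        poly = SupportTree(TreeNode(1.0, children=[
            TreeNode(0.0, name=n) for n in "ABC"]))
        p = write_newick(poly, tmp_path / "t.nwk")
        parsed = dendropy.Tree.get(path=str(p), schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == {"A", "B", "C"}

    def test_quoted_names_round_trip(self):
        t = SupportTree(TreeNode(1.0, children=[
            TreeNode(0.0, name="ds0|PR"), TreeNode(0.0, name="weird name")]))
        back = read_newick(t.newick())
        assert set(back.leaves()) == {"ds0|PR", "weird name"}

    def test_empty_tree_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_newick(SupportTree(TreeNode()), tmp_path / "x.nwk")
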