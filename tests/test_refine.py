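import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scatlas import (
    AtlasSimSpec,
    ClassSpec,
    CountMatrix,
    find_de_genes,
    flag_doublet_clusters,
    flag_low_quality_clusters,
    hurdle_de_test,
    merge_sibling_clusters,
    simulate_atlas,
)
from scatlas.embed import ClusterAssignment
from scatlas.preprocess import normalize_log, scale_genes, select_hvgs
from scatlas.simulate import marker_table_from_spec


@pytest.fixture(scope="module")
def one_type_nm():
    spec = AtlasSimSpec(n_genes=500, classes=[ClassSpec("A", 1, 0, 0)],
                        n_cells=300, seed=9)
    cm, _ = simulate_atlas(spec)
    return normalize_log(cm)


class TestHurdleDeTest:
    def test_random_split_is_calibrated(self, one_type_nm, rng):
        fracs = []
        for _ in range(3):
            perm = rng.permutation(300)
            de = hurdle_de_test(one_type_nm, perm[:150], perm[150:])
            fracs.append((de.table.pval < 0.05).mean())
        assert 0.02 < np.mean(fracs) < 0.09
        assert de.table.padj.min() > 0.05     # no FDR hits on a pure split

    def test_planted_fourfold_markers_detected(self):
        spec = AtlasSimSpec(n_genes=500, classes=[ClassSpec("A", 2, 0, 10)],
                            marker_fold=4.0, base_mean=0.5, n_cells=100, seed=5)
        cm, truth = simulate_atlas(spec)
        nm = normalize_log(cm)
        t = truth.table.type_label.to_numpy()
        de = hurdle_de_test(nm, np.flatnonzero(t == "A.t0"),
                            np.flatnonzero(t == "A.t1"))
        markers = de.table.iloc[:10]          # A.t0's planted markers
        assert (markers.padj < 0.01).all()
        assert (markers.log2fc > 0.5).all()

    def test_swap_symmetry(self, one_type_nm):
        a, b = np.arange(100), np.arange(100, 300)
        d1 = hurdle_de_test(one_type_nm, a, b)
        d2 = hurdle_de_test(one_type_nm, b, a)
        assert np.allclose(d1.table.pval, d2.table.pval, atol=1e-6)
        assert np.allclose(d1.table.log2fc, -d2.table.log2fc)

    def test_all_zero_gene_gets_p_one(self):
        dense = np.vstack([np.zeros(20), np.random.default_rng(0).poisson(5, 20)])
        cm = CountMatrix(sp.csr_matrix(dense), ["gz", "g1"],
                         [f"b{i}" for i in range(20)])
        nm = normalize_log(cm)
        de = hurdle_de_test(nm, np.arange(10), np.arange(10, 20))
        row = de.table.set_index("gene").loc["gz"]
        assert row.pval == 1.0 and row.log2fc == 0.0

    def test_small_group_rejected(self, one_type_nm):
        with pytest.raises(ValueError):
            hurdle_de_test(one_type_nm, np.arange(2), np.arange(2, 30))

    def test_padj_at_least_pval(self, one_type_nm):
        de = hurdle_de_test(one_type_nm, np.arange(150), np.arange(150, 300))
        assert (de.table.padj >= de.table.pval - 1e-12).all()


class TestFindDeGenes:
    def _frame(self, **kw):
        base = dict(gene=["g"], log2fc=[2.0], rate_a=[0.8], rate_b=[0.3],
                    pval=[1e-8], padj=[1e-6])
        base.update(kw)
        from scatlas.refine import DEResult

        return DEResult(pd.DataFrame(base))

    def test_dominant_gene_included(self):
        assert find_de_genes(self._frame()) == ["g"]

    def test_infinite_threshold_empties(self):
        assert find_de_genes(self._frame(), min_abs_log2fc=np.inf) == []

    def test_empty_result_empty_list(self):
        from scatlas.refine import DEResult

        empty = DEResult(pd.DataFrame(columns=["gene", "log2fc", "rate_a",
                                               "rate_b", "pval", "padj"]))
        assert find_de_genes(empty) == []

    def test_each_filter_is_applied(self):
        assert find_de_genes(self._frame(log2fc=[0.2])) == []
        assert find_de_genes(self._frame(padj=[0.5])) == []
        assert find_de_genes(self._frame(rate_a=[0.35])) == []


class TestDoubletFlags:
    @pytest.fixture(scope="class")
    def doublet_fit(self):
        from scatlas import AtlasModel, PipelineConfig

        spec = AtlasSimSpec(
            n_genes=900, classes=[ClassSpec("PR", 1), ClassSpec("RGC", 1),
                                  ClassSpec("MG", 1)],
            n_cells=1800, seed=13, doublet_rate=0.08,
        )
        model = AtlasModel.from_simulation(
            spec, config=PipelineConfig(min_genes_per_cell=0, rng_seed=13))
        return model, model.fit()

    def test_planted_doublet_clusters_flagged(self, doublet_fit):
        model, res = doublet_fit
        truth = model.ground_truth
        dbl = truth.table.set_index("cell").loc[res.assignment.cells, "doublet"]
        flagged = res.assignment.cell_status() == "doublet"
        assert flagged[dbl.to_numpy()].mean() > 0.6
        assert flagged[~dbl.to_numpy()].mean() < 0.05

    def test_no_flags_without_doublets(self, fitted_small):
        _, res = fitted_small
        assert "doublet" not in set(res.assignment.status.values())

    def test_umi_fold_boundary_respected(self):
        # a cluster at 1.4x the same-class median survives the 1.5-fold rule
        rng = np.random.default_rng(2)
        n = 90
        depth = np.concatenate([np.full(30, 100), np.full(30, 100), np.full(30, 140)])
        counts = rng.poisson(depth[None, :] * np.full((50, 1), 0.02 * 2))
        counts[:5, :] += rng.poisson(3.0, size=(5, n))      # shared markers
        cm = CountMatrix(sp.csr_matrix(counts), [f"g{i}" for i in range(50)],
                         [f"b{i}" for i in range(n)])
        nm = normalize_log(cm)
        assign = ClusterAssignment(cells=cm.cells,
                                   labels=np.repeat([0, 1, 2], 30), resolution=0.8)
        markers = {"X": {"g0", "g1", "g2", "g3", "g4"}}
        out = flag_doublet_clusters(cm, nm, assign, markers, umi_fold=1.5,
                                    arms=("umi",))
        assert set(out.status.values()) == {"kept"}


class TestLowQualityFlags:
    def _setup(self, scale_last=1.0, n_clusters=6, seed=4):
        rng = np.random.default_rng(seed)
        per = 40
        blocks, labels = [], []
        for c in range(n_clusters):
            lam = np.full((80, per), 1.0)
            if c == n_clusters - 1:
                lam *= scale_last
            blocks.append(rng.poisson(lam))
            labels += [c] * per
        dense = np.concatenate(blocks, axis=1)
        dense[:5] += rng.poisson(5.0, size=(5, dense.shape[1]))  # housekeeping
        cm = CountMatrix(sp.csr_matrix(dense), [f"g{i}" for i in range(80)],
                         [f"b{i}" for i in range(dense.shape[1])])
        nm = normalize_log(cm)
        assign = ClusterAssignment(cells=cm.cells, labels=np.array(labels),
                                   resolution=0.8)
        return cm, nm, assign

    def test_degraded_cluster_flagged(self):
        cm, nm, assign = self._setup(scale_last=0.2)
        out = flag_low_quality_clusters(cm, nm, assign,
                                        housekeeping={"g0", "g1", "g2"})
        assert out.status[5] == "low_quality"
        assert all(out.status[c] == "kept" for c in range(5))

    def test_homogeneous_clusters_unflagged(self):
        cm, nm, assign = self._setup(scale_last=1.0)
        out = flag_low_quality_clusters(cm, nm, assign,
                                        housekeeping={"g0", "g1", "g2"})
        assert set(out.status.values()) == {"kept"}

    def test_empty_housekeeping_rejected(self):
        cm, nm, assign = self._setup()
        with pytest.raises(ValueError):
            flag_low_quality_clusters(cm, nm, assign, housekeeping=set())

    def test_too_few_clusters_warns_and_skips(self):
        cm, nm, assign = self._setup(n_clusters=2)
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = flag_low_quality_clusters(cm, nm, assign, housekeeping={"g0"})
        assert set(out.status.values()) == {"kept"}


class TestMergeSiblingClusters:
    def test_artificial_split_repaired(self):
        spec = AtlasSimSpec(n_genes=600, classes=[ClassSpec("A", 2)],
                            n_cells=700, seed=17)
        cm, truth = simulate_atlas(spec)
        nm = normalize_log(cm)
        select_hvgs(nm, 600)
        scale_genes(nm)
        # over-split each true type in half by library size rank
        t = truth.table.type_label.to_numpy()
        umi = cm.umis_per_cell()
        labels = np.zeros(len(t), int)
        for i, ty in enumerate(np.unique(t)):
            idx = np.flatnonzero(t == ty)
            hi = idx[umi[idx] > np.median(umi[idx])]
            labels[idx] = 2 * i
            labels[hi] = 2 * i + 1
        assign = ClusterAssignment(cells=cm.cells, labels=labels, resolution=2.0)
        merged = merge_sibling_clusters(nm, assign)
        assert len(merged.kept_clusters()) == 2
        eff = merged.effective_labels()
        assert len(np.unique(eff[t == "A.t0"])) == 1
        assert len(np.unique(eff[t == "A.t1"])) == 1

    def test_distinct_types_never_merged(self, small_nm, small_sim):
        _, truth = small_sim
        codes, _ = pd.factorize(truth.table.type_label)
        assign = ClusterAssignment(cells=small_nm.cells, labels=codes,
                                   resolution=0.8)
        merged = merge_sibling_clusters(small_nm, assign)
        assert len(merged.kept_clusters()) == 8
        assert not any(a == "merged" for a in merged.status.values())

    def test_single_cluster_is_identity(self, small_nm):
        assign = ClusterAssignment(cells=small_nm.cells,
                                   labels=np.zeros(small_nm.n_cells, int),
                                   resolution=0.8)
        merged = merge_sibling_clusters(small_nm, assign)
        assert merged.kept_clusters() == [0]

    def test_status_partition_invariant(self, fitted_small):
        _, res = fitted_small
        statuses = set(res.assignment.status.values())
        assert statuses <= {"kept", "doublet", "low_quality", "merged"}
        # every cell resolves to a kept or flagged cluster, never a merged one
        eff = res.assignment.effective_labels()
        for c in np.unique(eff):
            assert res.assignment.status.get(int(c), "kept") != "merged"
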