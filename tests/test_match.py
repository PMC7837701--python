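import numpy as np
import pandas as pd
import pytest

from scatlas import (
    map_types,
    predict_and_confuse,
    train_cluster_classifier,
)
from scatlas.embed import ClusterAssignment
from scatlas.match import ConfusionMap


@pytest.fixture(scope="module")
def truth_assign(small_nm_module):
    nm, truth = small_nm_module
    codes, uniq = pd.factorize(truth.table.set_index("cell")
                               .loc[nm.cells, "type_label"])
    return ClusterAssignment(cells=list(nm.cells), labels=codes,
                             resolution=0.8), list(uniq)


@pytest.fixture(scope="module")
def small_nm_module(small_sim):
    from scatlas.preprocess import normalize_log

    cm, truth = small_sim
    return normalize_log(cm), truth


@pytest.fixture(scope="module")
def trained(small_nm_module, truth_assign):
    nm, _ = small_nm_module
    assign, _ = truth_assign
    return train_cluster_classifier(nm, assign, features=list(nm.genes), seed=3)


class TestTrainClassifier:
    def test_holdout_accuracy_high_on_separable_types(self, trained):
        assert trained.holdout_accuracy >= 0.9

    def test_fixed_seed_reproducible(self, small_nm_module, truth_assign):
        nm, _ = small_nm_module
        assign, _ = truth_assign
        a = train_cluster_classifier(nm, assign, features=list(nm.genes), seed=3)
        b = train_cluster_classifier(nm, assign, features=list(nm.genes), seed=3)
        x = np.random.default_rng(0).normal(size=(20, len(a.features)))
        assert np.array_equal(a.model.predict(x), b.model.predict(x))

    def test_identical_clusters_confuse_each_other(self, small_nm_module):
        nm, truth = small_nm_module
        # split one true type into two fake "clusters": held-out accuracy
        # between them is chance-level
        t = truth.table.set_index("cell").loc[nm.cells, "type_label"].to_numpy()
        idx = np.flatnonzero(t == t[0])
        labels = np.zeros(nm.n_cells, int)
        labels[idx[len(idx) // 2:]] = 1
        sub = nm.subset_cells(idx)
        sub_labels = labels[idx]
        assign = ClusterAssignment(cells=list(sub.cells), labels=sub_labels,
                                   resolution=0.8)
        clf = train_cluster_classifier(sub, assign, features=list(sub.genes),
                                       seed=0)
        assert clf.holdout_accuracy < 0.75

    def test_empty_features_rejected(self, small_nm_module, truth_assign):
        nm, _ = small_nm_module
        assign, _ = truth_assign
        with pytest.raises(ValueError):
            train_cluster_classifier(nm, assign, features=[], seed=0)


class TestPredictAndConfuse:
    def test_rows_sum_to_one(self, trained, small_nm_module, truth_assign):
        nm, _ = small_nm_module
        assign, _ = truth_assign
        conf = predict_and_confuse(trained, nm, assign)
        assert np.allclose(conf.matrix.sum(axis=1), 1.0)

    def test_self_mapping_recovers_identity(self, trained, small_nm_module,
                                            truth_assign):
        nm, _ = small_nm_module
        assign, _ = truth_assign
        conf = predict_and_confuse(trained, nm, assign)
        best = conf.best_matches()
        assert (best.index == best.reference).all()
        assert (best.confidence >= 0.7).all()

    def test_missing_features_beyond_20pct_rejected(self, trained,
                                                    small_nm_module,
                                                    truth_assign):
        nm, _ = small_nm_module
        assign, _ = truth_assign
        crippled = nm.subset_cells(np.arange(nm.n_cells))
        keep = int(len(trained.features) * 0.7)
        crippled.genes = list(nm.genes[:keep]) + [
            f"zz{i}" for i in range(nm.n_genes - keep)]
        with pytest.raises(ValueError, match="refusing"):
            predict_and_confuse(trained, crippled, assign)

    def test_column_equivariance_under_label_permutation(
            self, small_nm_module, truth_assign):
        nm, _ = small_nm_module
        assign, _ = truth_assign
        perm = {c: (c + 1) % len(assign.kept_clusters())
                for c in assign.kept_clusters()}
        permuted = ClusterAssignment(
            cells=list(assign.cells),
            labels=np.array([perm[int(l)] for l in assign.labels]),
            resolution=0.8)
        a = train_cluster_classifier(nm, assign, features=list(nm.genes), seed=1)
        b = train_cluster_classifier(nm, permuted, features=list(nm.genes), seed=1)
        ca = predict_and_confuse(a, nm, assign).matrix
        cb = predict_and_confuse(b, nm, permuted).matrix
        relabeled = cb.rename(index=lambda q: {v: k for k, v in perm.items()}[q],
                              columns=lambda r: {v: k for k, v in perm.items()}[r])
        relabeled = relabeled.sort_index().sort_index(axis=1)
        assert np.allclose(ca.to_numpy(), relabeled.to_numpy(), atol=0.05)


class TestMapTypes:
    def _conf(self, rows, queries, refs):
        return ConfusionMap(pd.DataFrame(rows, index=queries, columns=refs))

    def test_high_confidence_matched(self):
        conf = self._conf([[0.95, 0.05]], ["q0"], ["r0", "r1"])
        out = map_types(conf, 0.5)
        assert out.loc[0, "status"] == "matched"
        assert out.loc[0, "reference"] == "r0"

    def test_uniform_row_unmatched(self):
        conf = self._conf([np.full(10, 0.1)], ["q0"], [f"r{i}" for i in range(10)])
        assert map_types(conf, 0.5).loc[0, "status"] == "unmatched"

    def test_many_to_one_allowed(self):
        conf = self._conf([[0.9, 0.1], [0.8, 0.2]], ["q0", "q1"], ["r0", "r1"])
        out = map_types(conf, 0.5)
        assert (out.reference == "r0").all() and (out.status == "matched").all()
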