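"""Cross-dataset (species / age) harmonization and pooled comparison.

Datasets are placed on a shared gene space by mapping each dataset's gene
identifiers to homolog groups and keeping only groups present in every
dataset (multiple genes collapsing to one group are summed at the count
level, preserving UMI semantics).  Types are down-sampled to a per-type
cap before pooling, each dataset is log-normalized and gene-wise z-scaled
separately (no anchor-based correction), and pooled (dataset, type)
profiles feed the resampled-consensus dendrogram machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, PipelineConfig, stage_seed
from .preprocess import normalize_log
from .trees import SupportTree, consensus_tree, linkage_tree


@dataclass
class HarmonizedPool:
    """Shared-homolog-group expression across pooled datasets.

    ``values`` is the per-dataset z-scaled log expression (groups x pooled
    cells); ``meta`` carries dataset id and original type label per cell.
    """

    values: np.ndarray
    groups: list[str]
    meta: pd.DataFrame  # columns: cell, dataset, type_label

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def harmonize_genes(
    datasets: list[CountMatrix],
    homologs: dict[str, dict[str, str]],
    dataset_names: list[str] | None = None,
) -> list[CountMatrix]:
    """Re-key each dataset's genes to homolog groups shared by ALL datasets.

    Genes without a homolog entry are dropped; several genes in one group
    are collapsed by summing counts before any normalization.  Zero shared
    groups is an error.
    """
    if dataset_names is None:
        dataset_names = [
            (cm.meta["dataset"].iloc[0] if cm.meta is not None and "dataset" in cm.meta
             else f"ds{i}")
            for i, cm in enumerate(datasets)
        ]
    per_ds_groups = []
    for name, cm in zip(dataset_names, datasets):
        gmap = homologs.get(name, {})
        per_ds_groups.append({gmap[g] for g in cm.genes if g in gmap})
    shared = set.intersection(*per_ds_groups) if per_ds_groups else set()
    if not shared:
        raise ValueError("no homolog group shared by all datasets")
    shared = sorted(shared)
    pos = {grp: i for i, grp in enumerate(shared)}

    out = []
    for name, cm in zip(dataset_names, datasets):
        gmap = homologs.get(name, {})
        rows, cols, keep = [], [], []
        for gi, g in enumerate(cm.genes):
            grp = gmap.get(g)
            if grp in pos:
                keep.append(gi)
                rows.append(pos[grp])
        sel = cm.counts[keep, :]
        agg = sp.csr_matrix(
            (np.ones(len(keep)), (rows, np.arange(len(keep)))),
            shape=(len(shared), len(keep)),
        )
        collapsed = agg @ sel          # sums genes within a group
        out.append(CountMatrix(
            counts=sp.csr_matrix(collapsed), genes=shared, cells=cm.cells, meta=cm.meta,
        ))
    return out


def build_pool(
    harmonized: list[CountMatrix],
    type_labels: list[np.ndarray],
    scale_factor: int = 10_000,
    cap: float = 10.0,
    dataset_names: list[str] | None = None,
) -> HarmonizedPool:
    """Log-normalize and gene-wise z-scale each dataset, then concatenate."""
    if dataset_names is None:
        dataset_names = [f"ds{i}" for i in range(len(harmonized))]
    blocks, meta_rows = [], []
    for name, cm, labels in zip(dataset_names, harmonized, type_labels):
        nm = normalize_log(cm, scale_factor=scale_factor)
        dense = np.asarray(nm.values.todense(), dtype=float)
        mu = dense.mean(axis=1, keepdims=True)
        sd = dense.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = np.clip((dense - mu) / sd, -cap, cap)
        blocks.append(z)
        for cell, lab in zip(cm.cells, labels):
            meta_rows.append({"cell": cell, "dataset": name, "type_label": str(lab)})
    return HarmonizedPool(
        values=np.concatenate(blocks, axis=1),
        groups=list(harmonized[0].genes),
        meta=pd.DataFrame(meta_rows),
    )


def downsample_types(pool: HarmonizedPool, max_per_type: int = 200,
                     seed: int = 0) -> HarmonizedPool:
    """Cap each (dataset, type) at ``max_per_type`` cells, sampled without replacement."""
    if not np.isfinite(max_per_type):
        return pool
    rng = np.random.default_rng(seed)
    keep = []
    for _, idx in pool.meta.groupby(["dataset", "type_label"]).groups.items():
        idx = np.asarray(idx)
        if idx.size > max_per_type:
            idx = rng.choice(idx, size=int(max_per_type), replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return HarmonizedPool(
        values=pool.values[:, keep],
        groups=pool.groups,
        meta=pool.meta.iloc[keep].reset_index(drop=True),
    )


def pooled_class_tree(
    pool: HarmonizedPool,
    cfg: PipelineConfig | None = None,
    min_cells_per_leaf: int = 5,
) -> SupportTree:
    """Consensus dendrogram over (dataset, type) profiles of the pool.

    100 builds by default, each on 80% of cells and 80% of genes, combined
    by majority rule; leaves with fewer than ``min_cells_per_leaf`` cells
    are dropped with a warning.
    """
    cfg = cfg or PipelineConfig()
    labels = pool.meta["dataset"] + "|" + pool.meta["type_label"]
    groups = labels.groupby(labels).groups
    leaf_cells = {}
    for name, idx in groups.items():
        if len(idx) < min_cells_per_leaf:
            warnings.warn(f"leaf {name} has {len(idx)} cells (<{min_cells_per_leaf}); dropped",
                          stacklevel=2)
            continue
        leaf_cells[name] = np.asarray(idx)
    if len(leaf_cells) < 2:
        raise ValueError("fewer than 2 leaves with enough cells")
    names = sorted(leaf_cells)
    rng = np.random.default_rng(stage_seed(cfg.rng_seed, "pooled_tree"))
    n_genes, _ = pool.values.shape
    trees = []
    for _ in range(cfg.n_tree_builds):
        genes = rng.choice(n_genes, size=max(int(cfg.tree_gene_frac * n_genes), 2),
                           replace=False)
        rows = []
        for name in names:
            idx = leaf_cells[name]
            take = rng.choice(idx, size=max(int(cfg.tree_cell_frac * idx.size), 1),
                              replace=False)
            rows.append(pool.values[np.ix_(genes, take)].mean(axis=1))
        trees.append(linkage_tree(pd.DataFrame(rows, index=names)))
    return consensus_tree(trees)
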