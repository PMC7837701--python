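"""Reusable pipeline stages shared by the model front end and the saturation test."""

from __future__ import annotations

import numpy as np

from .embed import (
    ClusterAssignment,
    PCModel,
    build_knn_graph,
    cluster_communities,
    count_significant_pcs_tw,
    run_pca,
)
from .io import PipelineConfig, stage_seed
from .preprocess import NormalizedMatrix, scale_genes, select_hvgs


def cluster_stage(
    nm: NormalizedMatrix, cfg: PipelineConfig, seed: int
) -> tuple[ClusterAssignment, PCModel]:
    """HVG selection -> scaling -> PCA -> Tracy-Widom -> SNN graph -> Leiden.

    Mutates ``nm`` in place (hvg_mask, scaled block) and returns the
    community assignment plus the PC model with ``n_significant`` set
    (floored at ``cfg.min_significant_pcs``).
    """
    select_hvgs(nm, n_hvgs=cfg.n_hvgs)
    scale_genes(nm, cap=cfg.scale_cap)
    k = min(cfg.max_pcs, nm.scaled.shape[0], nm.n_cells - 1)
    pcs = run_pca(nm, k=k, seed=stage_seed(seed, "pca"))
    n_hvg = int(nm.hvg_mask.sum())
    n_sig = count_significant_pcs_tw(
        pcs.eigenvalues, n_cells=nm.n_cells, n_genes=n_hvg, alpha=cfg.tw_alpha,
        trace=float(np.sum(nm.scaled.var(axis=1, ddof=1))),
    )
    pcs.n_significant = max(n_sig, min(cfg.min_significant_pcs, k))
    graph = build_knn_graph(pcs.scores, n_pcs=pcs.n_significant,
                            k_neighbors=min(cfg.k_neighbors, nm.n_cells - 1))
    assign = cluster_communities(
        graph, resolution=cfg.cluster_resolution,
        seed=stage_seed(seed, "leiden"), cells=nm.cells,
    )
    return assign, pcs
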