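"""Model/Results front end orchestrating the full atlas pipeline.

:class:`AtlasModel` bundles a count matrix with a :class:`PipelineConfig`
and optional marker / housekeeping gene sets; ``fit()`` runs cell QC,
normalization, HVG selection, PCA with Tracy-Widom component selection,
SNN-Leiden clustering, doublet and low-quality cluster flagging,
DE-guided merging, class annotation and dendrogram construction, and
returns an :class:`AtlasResults` carrying every intermediate of interest,
a run manifest, and a ``summary()`` table.  One root seed fans out to
per-stage child seeds by stable hashing, so any stage is reproducible in
isolation.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._pipeline import cluster_stage
from .annotate import ClassAssignment, assign_classes, class_composition, score_class_markers
from .embed import ClusterAssignment, PCModel
from .io import (
    CountMatrix,
    PipelineConfig,
    read_counts_mtx,
    stage_seed,
    write_cluster_table,
)
from .preprocess import NormalizedMatrix, filter_cells, filter_genes, normalize_log
from .refine import flag_doublet_clusters, flag_low_quality_clusters, merge_sibling_clusters
from .trees import SupportTree, multiscale_bootstrap_support, write_newick


def _subcluster_by_class(nm, assign, class_assign, cfg, root_seed):
    """Re-cluster each annotated class's cells individually (no merging here).

    Doublet / low-quality clusters keep their flags and ids; kept cells are
    re-labeled from the per-class analyses, final ids 0..K-1 by descending
    size with flagged clusters renumbered after them.
    """
    cls_of = class_assign.cluster_classes()
    new_labels = np.full(len(assign.cells), -1, dtype=int)
    next_id = 0
    for cls in sorted(set(cls_of.loc[assign.kept_clusters()])):
        members = [c for c in assign.kept_clusters() if cls_of.get(c) == cls]
        idx = np.concatenate([assign.cluster_cells(c) for c in members])
        if idx.size < 3 * cfg.k_neighbors:
            new_labels[idx] = next_id      # too small to re-analyze; one cluster
            next_id += 1
            continue
        sub = nm.subset_cells(idx)
        sub.hvg_mask = None
        sub.scaled = None
        sub_assign, _ = cluster_stage(sub, cfg, stage_seed(root_seed, f"sub:{cls}"))
        eff = sub_assign.labels
        remap = {k: next_id + i for i, k in enumerate(sorted(set(eff)))}
        new_labels[idx] = [remap[e] for e in eff]
        next_id += len(remap)
    status = {}
    for c in assign.cluster_ids():
        st = assign.status.get(c, "kept")
        if st in ("doublet", "low_quality"):
            idx = assign.cluster_cells(c)
            new_labels[idx] = next_id
            status[next_id] = st
            next_id += 1
    # order kept clusters by size for stable, size-ranked ids
    kept_ids = [c for c in np.unique(new_labels) if status.get(int(c), "kept") == "kept"]
    sizes = {c: int((new_labels == c).sum()) for c in kept_ids}
    order = sorted(kept_ids, key=lambda c: (-sizes[c], c))
    final_map = {old: new for new, old in enumerate(order)}
    offset = len(order)
    for c in np.unique(new_labels):
        if int(c) not in final_map:
            final_map[int(c)] = offset
            offset += 1
    final_labels = np.array([final_map[int(c)] for c in new_labels])
    final_status = {final_map[c]: st for c, st in status.items()}
    return ClusterAssignment(
        cells=list(assign.cells), labels=final_labels,
        resolution=assign.resolution, status=final_status,
    )


class AtlasModel:
    """Atlas-construction model over a gene x cell UMI count matrix.

    Parameters
    ----------
    counts
        The raw count matrix.
    config
        Pipeline constants; defaults are the published protocol values.
    markers
        class -> marker-gene-set map used for doublet flagging and class
        annotation; omit to skip annotation.
    housekeeping
        Gene set for the low-quality cluster rule; omit to skip it.
    """

    def __init__(
        self,
        counts: CountMatrix,
        config: PipelineConfig | None = None,
        markers: dict[str, set[str]] | None = None,
        housekeeping: set[str] | None = None,
    ):
        self.counts = counts
        self.config = config or PipelineConfig()
        self.markers = markers
        self.housekeeping = housekeeping

    @classmethod
    def from_mtx_dir(cls, path, config=None, markers=None, housekeeping=None):
        return cls(read_counts_mtx(path), config=config, markers=markers,
                   housekeeping=housekeeping)

    @classmethod
    def from_simulation(cls, spec, config=None, use_spec_markers: bool = True):
        """Build from a simulated atlas; ground truth is attached to the model."""
        from .simulate import marker_table_from_spec, simulate_atlas

        cm, truth = simulate_atlas(spec)
        markers = marker_table_from_spec(spec) if use_spec_markers else None
        m = cls(cm, config=config, markers=markers)
        m.ground_truth = truth
        return m

    def fit(
        self,
        seed: int | None = None,
        compute_tree_support: bool = False,
        subcluster_within_classes: bool = True,
    ) -> "AtlasResults":
        """Run the full pipeline; deterministic given the seed.

        With ``subcluster_within_classes`` (and a marker map) each
        annotated class is re-analyzed individually — fresh HVGs, PCA,
        graph clustering and DE-guided merging on that class's cells —
        which maximizes the dynamic range of the feature space within a
        class and resolves types a single global pass fuses.  Without
        markers the global pass plus merge is used as-is.
        """
        cfg = self.config
        root = cfg.rng_seed if seed is None else int(seed)
        timings: dict[str, float] = {}
        t0 = time.perf_counter()

        def tick(stage: str) -> None:
            nonlocal t0
            now = time.perf_counter()
            timings[stage] = round(now - t0, 3)
            t0 = now

        filtered = filter_cells(self.counts, cfg.min_genes_per_cell)
        filtered = filter_genes(filtered, getattr(cfg, "min_cells_per_gene", 0))
        if filtered.n_cells == 0:
            raise ValueError("no cell passed QC")
        tick("filter")

        nm = normalize_log(filtered, scale_factor=cfg.scale_factor)
        tick("normalize")

        assign, pcs = cluster_stage(nm, cfg, root)
        tick("cluster")

        de_thresholds = {
            "min_abs_log2fc": cfg.de_min_abs_log2fc,
            "max_adj_p": cfg.de_max_adj_p,
            "min_rate_diff": cfg.de_min_rate_diff,
            "de_min_genes": cfg.de_min_genes,
        }
        if subcluster_within_classes and self.markers:
            first_pass = assign_classes(score_class_markers(nm, assign, self.markers))
            assign = _subcluster_by_class(nm, assign, first_pass, cfg, root)
        tick("subcluster")

        # contaminant-like clusters become evident only after the fine division;
        # flagging precedes merging so depth-doubled doublet subclusters are
        # caught before the merge step would absorb them
        if self.markers:
            assign = flag_doublet_clusters(
                filtered, nm, assign, self.markers, umi_fold=cfg.doublet_umi_fold,
            )
        if self.housekeeping:
            assign = flag_low_quality_clusters(filtered, nm, assign, self.housekeeping)
        tick("flag")

        assign = merge_sibling_clusters(nm, assign, de_thresholds=de_thresholds)
        tick("merge")

        class_assign = None
        composition = None
        if self.markers:
            scores = score_class_markers(nm, assign, self.markers)
            class_assign = assign_classes(scores)
            composition = class_composition(assign, class_assign)
        tick("annotate")

        tree = None
        if len(assign.kept_clusters()) >= 2:
            if compute_tree_support:
                tree = multiscale_bootstrap_support(
                    nm, assign, seed=stage_seed(root, "tree_support"),
                )
            else:
                from .trees import cluster_profiles, linkage_tree

                tree = linkage_tree(cluster_profiles(nm, assign))
        tick("tree")

        manifest = {
            "config": cfg.to_json(),
            "root_seed": root,
            "stage_seeds": {s: stage_seed(root, s) for s in
                            ("pca", "leiden", "tree_support")},
            "n_cells_in": self.counts.n_cells,
            "n_cells_kept": filtered.n_cells,
            "timings_s": timings,
        }
        return AtlasResults(
            model=self, counts=filtered, normalized=nm, pcs=pcs,
            assignment=assign, class_assignment=class_assign,
            composition=composition, tree=tree, manifest=manifest,
            de_thresholds=de_thresholds,
        )


@dataclass
class AtlasResults:
    """Fitted atlas: assignments, annotation, tree, and run metadata."""

    model: AtlasModel
    counts: CountMatrix
    normalized: NormalizedMatrix
    pcs: PCModel
    assignment: ClusterAssignment
    class_assignment: ClassAssignment | None
    composition: tuple | None
    tree: SupportTree | None
    manifest: dict
    de_thresholds: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.assignment.kept_clusters())

    def cluster_table(self) -> pd.DataFrame:
        return self.assignment.to_frame()

    def summary(self) -> str:
        a = self.assignment
        status = pd.Series(a.status)
        lines = [
            "Atlas pipeline summary",
            "=" * 54,
            f"cells in / after QC      {self.model.counts.n_cells:>7d} / {self.counts.n_cells}",
            f"HVGs / significant PCs   {int(self.normalized.hvg_mask.sum()):>7d} / {self.pcs.n_significant}",
            f"initial clusters         {len(a.cluster_ids()):>7d}",
            f"  kept                   {self.n_clusters:>7d}",
            f"  doublet-flagged        {(status == 'doublet').sum():>7d}",
            f"  low-quality            {(status == 'low_quality').sum():>7d}",
            f"  merged away            {(status == 'merged').sum():>7d}",
        ]
        if self.class_assignment is not None:
            per_class, _ = self.composition
            lines.append("class composition (% of kept cells)")
            for cls, row in per_class.iterrows():
                lines.append(f"  {cls:<12s} {int(row.n_cells):>6d}  {row.pct_of_total:>5.1f}%")
        return "\n".join(lines)

    def saturation(self, **kw):
        """Run the down-sampling cluster-saturation test on the fitted data."""
        from .saturation import downsample_cluster_counts

        nm = self.normalized.subset_cells(np.arange(self.normalized.n_cells))
        return downsample_cluster_counts(nm, self.model.config,
                                         de_thresholds=self.de_thresholds, **kw)

    def to_dir(self, outdir) -> Path:
        """Write TSV/newick artifacts and the manifest."""
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cluster_table(self.assignment, outdir / "clusters.tsv")
        pd.DataFrame(self.pcs.scores).to_csv(outdir / "pc_scores.tsv", sep="\t",
                                             index=False, header=False)
        if self.class_assignment is not None:
            self.class_assignment.table.to_csv(outdir / "cluster_classes.tsv", sep="\t")
            per_class, per_cluster = self.composition
            per_class.to_csv(outdir / "class_composition.tsv", sep="\t")
            per_cluster.to_csv(outdir / "cluster_composition.tsv", sep="\t")
        if self.tree is not None:
            write_newick(self.tree, outdir / "cluster_tree.nwk")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return outdir


def run_atlas(config_path, mtx_dir=None, outdir="atlas_out",
              markers=None, housekeeping=None) -> dict:
    """File-driven end-to-end run: config in, artifacts + manifest out."""
    cfg = PipelineConfig.from_file(config_path)
    if mtx_dir is None:
        raise ValueError("an input MTX directory is required")
    model = AtlasModel.from_mtx_dir(mtx_dir, config=cfg, markers=markers,
                                    housekeeping=housekeeping)
    res = model.fit()
    res.to_dir(outdir)
    return res.manifest
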