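"""Marker-based class annotation of clusters and composition tables.

Classes are assigned at the cluster level: each kept cluster is scored
against every class's canonical marker set (mean of per-gene z-scaled
cluster-mean expression) and labeled with the argmax, with small-margin
calls reported as ambiguous.  Cells inherit their cluster's class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embed import ClusterAssignment
from .preprocess import NormalizedMatrix
from .refine import marker_score_matrix


@dataclass
class ClassAssignment:
    """Per-cluster class labels with marker scores and assignment margins."""

    table: pd.DataFrame  # index cluster; columns: class_label, margin + score columns

    def class_of(self, cluster: int) -> str:
        return str(self.table.loc[cluster, "class_label"])

    def cluster_classes(self) -> pd.Series:
        return self.table["class_label"]


def score_class_markers(
    nm: NormalizedMatrix,
    assign: ClusterAssignment,
    markers: dict[str, set[str]],
) -> pd.DataFrame:
    """cluster x class marker-score matrix (kept clusters only).

    Marker genes missing from the matrix warn; a class with no resolvable
    marker yields a NaN column.
    """
    if not markers:
        raise ValueError("marker map is empty")
    return marker_score_matrix(nm, assign, markers)


def assign_classes(scores: pd.DataFrame, min_margin: float = 0.1) -> ClassAssignment:
    """Argmax class per cluster; margin (top - second) below ``min_margin``
    is labeled ``ambiguous``; an all-NaN score row is ``unassigned``."""
    labels, margins = [], []
    for _, row in scores.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.all(np.isnan(vals)):
            labels.append("unassigned")
            margins.append(np.nan)
            continue
        order = np.argsort(np.nan_to_num(vals, nan=-np.inf))[::-1]
        top = vals[order[0]]
        second = vals[order[1]] if len(vals) > 1 and np.isfinite(vals[order[1]]) else -np.inf
        margin = top - second
        labels.append(scores.columns[order[0]] if margin >= min_margin else "ambiguous")
        margins.append(margin)
    table = scores.copy()
    table.insert(0, "class_label", labels)
    table.insert(1, "margin", margins)
    return ClassAssignment(table=table)


def class_composition(
    assign: ClusterAssignment, class_assign: ClassAssignment
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class- and cluster-level frequency tables over kept cells.

    Returns (per_class, per_cluster): per class, cell count and percent of
    all kept cells; per cluster, cell count and percent within its class,
    both to one decimal.  Percentages within a class sum to 100 up to
    rounding.
    """
    eff = assign.effective_labels()
    kept = assign.kept_cell_mask()
    cluster_class = class_assign.cluster_classes()
    labels = eff[kept]
    n_total = int(kept.sum())
    per_cluster_count = pd.Series(labels).value_counts().sort_index()
    rows = []
    for c, n in per_cluster_count.items():
        cls = cluster_class.get(c, "unassigned")
        rows.append({"cluster": int(c), "class_label": cls, "n_cells": int(n)})
    per_cluster = pd.DataFrame(rows).set_index("cluster")
    class_totals = per_cluster.groupby("class_label")["n_cells"].sum()
    per_cluster["pct_of_class"] = [
        round(100.0 * r.n_cells / class_totals[r.class_label], 1)
        for r in per_cluster.itertuples()
    ]
    per_class = pd.DataFrame({
        "n_cells": class_totals,
        "pct_of_total": (100.0 * class_totals / max(n_total, 1)).round(1),
    })
    return per_class, per_cluster
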