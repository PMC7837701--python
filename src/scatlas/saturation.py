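"""Cluster-number saturation under cell down-sampling.

Random subsets of 10-90% of cells are re-clustered with the same pipeline
(HVGs re-selected per subset, Tracy-Widom PC choice, graph clustering,
DE-guided merging), 10 repeats per fraction, and the final kept-cluster
count is recorded.  A plateau at the full-data count indicates that
sampling depth is no longer limiting type discovery; rare types reveal
themselves by depressed counts at small fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._pipeline import cluster_stage
from .io import PipelineConfig, stage_seed
from .preprocess import NormalizedMatrix
from .refine import merge_sibling_clusters


@dataclass
class SaturationCurve:
    """Cluster counts per (fraction, repeat) plus the full-data reference count."""

    table: pd.DataFrame  # columns: fraction, repeat, k
    k_full: int

    def summary_frame(self) -> pd.DataFrame:
        g = self.table.groupby("fraction")["k"]
        return pd.DataFrame({"mean_k": g.mean(), "sd_k": g.std(ddof=1).fillna(0.0),
                             "n_reps": g.size()})


def _subset_cluster_count(
    nm: NormalizedMatrix, cell_idx: np.ndarray, cfg: PipelineConfig, seed: int,
    de_thresholds: dict | None,
) -> int:
    sub = nm.subset_cells(cell_idx)
    sub.hvg_mask = None       # HVGs re-selected per subset
    sub.scaled = None
    assign, _ = cluster_stage(sub, cfg, seed)
    assign = merge_sibling_clusters(sub, assign, de_thresholds=de_thresholds)
    return len(assign.kept_clusters())


def downsample_cluster_counts(
    nm: NormalizedMatrix,
    cfg: PipelineConfig,
    de_thresholds: dict | None = None,
    min_cells: int = 50,
) -> SaturationCurve:
    """Re-cluster random cell subsets across ``cfg.saturation_fracs``.

    Each (fraction, repeat) draws cells without replacement with a seed
    derived deterministically from (cfg.rng_seed, fraction, repeat); the
    full-data count uses the same code path at fraction 1.0.  Subsets
    below ``min_cells`` cells are skipped with a warning.
    """
    n = nm.n_cells
    rows = []
    k_full = _subset_cluster_count(
        nm, np.arange(n), cfg, stage_seed(cfg.rng_seed, "saturation:1.0"),
        de_thresholds,
    )
    rows.append({"fraction": 1.0, "repeat": 0, "k": k_full})
    for frac in cfg.saturation_fracs:
        if frac >= 1.0:
            continue
        size = int(round(frac * n))
        if size < min_cells:
            warnings.warn(f"fraction {frac} gives {size} cells (<{min_cells}); skipped",
                          stacklevel=2)
            continue
        for rep in range(cfg.saturation_reps):
            seed = stage_seed(cfg.rng_seed, f"saturation:{frac}:{rep}")
            idx = np.random.default_rng(seed).choice(n, size=size, replace=False)
            k = _subset_cluster_count(nm, idx, cfg, seed, de_thresholds)
            rows.append({"fraction": float(frac), "repeat": rep, "k": k})
    return SaturationCurve(table=pd.DataFrame(rows), k_full=k_full)


def saturation_summary(curve: SaturationCurve, tol: float = 0.0) -> dict:
    """Smallest fraction whose mean count is within ``tol`` of the full-data count.

    Returns a dict with the per-fraction mean/SD frame, ``k_full`` and
    ``saturated_at`` (None when no fraction qualifies).
    """
    sf = curve.summary_frame()
    sub = sf[sf.index < 1.0]
    ok = sub[np.abs(sub["mean_k"] - curve.k_full) <= tol]
    saturated_at = float(ok.index.min()) if len(ok) else None
    return {"summary": sf, "k_full": curve.k_full, "saturated_at": saturated_at}
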