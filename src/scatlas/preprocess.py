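"""Cell QC, log-normalization, HVG selection and gene scaling.

Normalization follows the droplet convention: each cell's counts are
divided by its total, multiplied by a fixed scale factor (default 10,000)
and log1p-transformed (natural log).  Highly variable genes are ranked by
mean-binned dispersion (variance/mean, z-scored within 20 equal-width
log-mean bins), and scaled genes are unit-variance, zero-mean, clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix


@dataclass
class NormalizedMatrix:
    """Log-normalized expression with optional HVG mask and scaled HVG block.

    ``values`` stays sparse (zeros map to zero under log1p).  After
    :func:`scale_genes`, the HVG rows are additionally available densely in
    ``scaled`` (HVG x cells, clipped z-scores), with the per-gene centering
    and scaling parameters stored for reuse on query datasets.
    """

    values: sp.csr_matrix            # genes x cells, ln(1 + cp10k)
    genes: list[str]
    cells: list[str]
    hvg_mask: np.ndarray | None = None
    scaled: np.ndarray | None = None      # n_hvg x n_cells
    scale_means: np.ndarray | None = None
    scale_stds: np.ndarray | None = None
    scale_cap: float | None = None
    meta: pd.DataFrame | None = None

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def hvg_genes(self) -> list[str]:
        if self.hvg_mask is None:
            raise ValueError("HVGs not selected yet")
        return [g for g, m in zip(self.genes, self.hvg_mask) if m]

    def is_scaled(self) -> bool:
        return self.scaled is not None

    def subset_cells(self, idx) -> "NormalizedMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            values=self.values[:, idx],
            genes=self.genes,
            cells=[self.cells[i] for i in idx],
            hvg_mask=None if self.hvg_mask is None else self.hvg_mask.copy(),
            scaled=None if self.scaled is None else self.scaled[:, idx],
            scale_means=self.scale_means,
            scale_stds=self.scale_stds,
            scale_cap=self.scale_cap,
            meta=None if self.meta is None else self.meta.iloc[idx],
        )


def filter_cells(m: CountMatrix, min_genes: int) -> CountMatrix:
    """Keep cells detecting at least ``min_genes`` genes (count > 0); order preserved.

    Idempotent; an all-removed result is a valid empty matrix (warned).
    """
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    keep = m.genes_per_cell() >= min_genes
    if not keep.any():
        warnings.warn("cell filter removed every cell", stacklevel=2)
    return m.subset_cells(keep)


def filter_genes(m: CountMatrix, min_cells: int) -> CountMatrix:
    """Optional gene QC: keep genes detected in at least ``min_cells`` cells."""
    if min_cells <= 0:
        return m
    keep = np.asarray((m.counts > 0).sum(axis=1)).ravel() >= min_cells
    return m.subset_genes(keep)


def normalize_log(m: CountMatrix, scale_factor: int = 10_000) -> NormalizedMatrix:
    """ln(1 + scale_factor * count / cell_total), natural log, sparse.

    Cells with zero total are an error (run :func:`filter_cells` first);
    the message names the offending barcode.
    """
    totals = m.umis_per_cell().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell {m.cells[zero[0]]!r} has zero total count; filter cells first"
        )
    x = sp.csc_matrix(m.counts, dtype=float)
    x = x.multiply(scale_factor / totals[None, :]).tocsr()
    x.data = np.log1p(x.data)
    return NormalizedMatrix(
        values=x, genes=list(m.genes), cells=list(m.cells),
        meta=m.meta.copy() if m.meta is not None else None,
    )


def _dispersion_zscores(values: sp.csr_matrix, n_bins: int = 20) -> np.ndarray:
    """Variance/mean dispersion z-scored within equal-width log-mean bins."""
    n = values.shape[1]
    mean = np.asarray(values.mean(axis=1)).ravel()
    sq = np.asarray(values.multiply(values).mean(axis=1)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    logmean = np.log1p(mean)
    edges = np.linspace(logmean.min(), logmean.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(logmean, edges) - 1, 0, n_bins - 1)
    z = np.zeros_like(disp)
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        mu, sd = disp[sel].mean(), disp[sel].std()
        z[sel] = (disp[sel] - mu) / sd if sd > 0 else 0.0
    return z


def select_hvgs(nm: NormalizedMatrix, n_hvgs: int = 2000, n_bins: int = 20) -> NormalizedMatrix:
    """Mark the ``n_hvgs`` most over-dispersed genes (ties broken by gene order)."""
    if nm.n_cells < 2:
        raise ValueError("HVG selection needs at least 2 cells")
    if n_hvgs > nm.n_genes:
        warnings.warn(
            f"n_hvgs={n_hvgs} exceeds gene count {nm.n_genes}; capping", stacklevel=2
        )
        n_hvgs = nm.n_genes
    z = _dispersion_zscores(nm.values, n_bins=n_bins)
    order = np.argsort(-z, kind="stable")       # stable: ties keep gene order
    mask = np.zeros(nm.n_genes, bool)
    mask[order[:n_hvgs]] = True
    nm.hvg_mask = mask
    nm.scaled = None
    return nm


def scale_genes(nm: NormalizedMatrix, cap: float = 10.0) -> NormalizedMatrix:
    """Center/scale each HVG row to mean 0, unit variance, clipped to +-cap.

    Zero-variance HVGs become all-zero rows (warned).  Non-HVG rows are
    untouched; the dense scaled block lives in ``nm.scaled``.
    """
    if nm.hvg_mask is None:
        raise ValueError("select HVGs before scaling")
    hvg_idx = np.flatnonzero(nm.hvg_mask)
    dense = np.asarray(nm.values[hvg_idx, :].todense(), dtype=float)
    means = dense.mean(axis=1)
    stds = dense.std(axis=1)      # population sd: scaled rows have variance 1
    flat = stds == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance HVG rows set to 0", stacklevel=2)
    safe = np.where(flat, 1.0, stds)
    scaled = (dense - means[:, None]) / safe[:, None]
    scaled[flat, :] = 0.0
    np.clip(scaled, -cap, cap, out=scaled)
    nm.scaled = scaled
    nm.scale_means = means
    nm.scale_stds = safe
    nm.scale_cap = cap
    return nm
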