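"""Cluster-level QC (doublets, low quality) and DE-guided iterative merging.

Differential expression between two cell groups uses a two-part hurdle
test: a binomial likelihood-ratio test on the detection (on/off) pattern
plus a Gaussian likelihood-ratio test on log-expression among detecting
cells, summed into one chi-square statistic (df 2, or 1 when a component
is degenerate) and Benjamini-Hochberg adjusted across genes.  Clusters
that are siblings on the expression dendrogram are merged whenever no gene
passes the DE thresholds, repeating until a full pass makes no merge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2, median_abs_deviation
from statsmodels.stats.multitest import multipletests

from .embed import ClusterAssignment
from .io import CountMatrix
from .preprocess import NormalizedMatrix

LN2 = float(np.log(2.0))


@dataclass
class DEResult:
    """Per-gene differential-expression summary between groups A and B."""

    table: pd.DataFrame  # gene, log2fc, rate_a, rate_b, pval, padj

    def __len__(self) -> int:
        return len(self.table)


def _batched_logistic_loglik(
    x: np.ndarray, y: np.ndarray, n_iter: int = 30, tol: float = 1e-8,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Maximized Bernoulli log-likelihood of per-gene logistic fits.

    ``x`` is the shared n x p design, ``y`` an n x G detection matrix; one
    Newton/IRLS fit per gene, vectorized across genes.  Linear predictors
    are clipped so perfectly separated genes converge to their likelihood
    limit instead of overflowing.
    """
    n, p = x.shape
    g = y.shape[1]
    beta = np.zeros((p, g))
    # intercept at the empirical logit
    rate = np.clip(y.mean(axis=0), 1e-6, 1 - 1e-6)
    beta[0] = np.log(rate / (1 - rate))
    eye = ridge * np.eye(p)
    for _ in range(n_iter):
        eta = np.clip(x @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = x.T @ (y - mu)                        # p x G
        w = mu * (1.0 - mu)                          # n x G
        hess = np.einsum("ni,ng,nj->gij", x, w, x) + eye
        delta = np.linalg.solve(hess, grad.T[:, :, None])[:, :, 0].T
        beta += delta
        if np.max(np.abs(delta)) < tol:
            break
    eta = np.clip(x @ beta, -30.0, 30.0)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    return np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu), axis=0)


def _masked_wls_rss(x: np.ndarray, y: np.ndarray, mask: np.ndarray,
                    ridge: float = 1e-10) -> np.ndarray:
    """Per-gene residual sum of squares of y ~ x restricted to masked cells."""
    p = x.shape[1]
    xtx = np.einsum("ni,ng,nj->gij", x, mask, x) + ridge * np.eye(p)
    my = mask * y
    xty = np.einsum("ni,ng->gi", x, my)
    beta = np.linalg.solve(xtx, xty[:, :, None])[:, :, 0]
    fit = np.einsum("gi,gi->g", beta, xty)
    return np.maximum(np.einsum("ng,ng->g", my, y) - fit, 0.0)


def hurdle_de_test(
    nm: NormalizedMatrix,
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    adjust_cdr: bool = True,
) -> DEResult:
    """Two-part hurdle GLM likelihood-ratio test per gene between groups A and B.

    Detection component: logistic model of the on/off pattern, LRT for the
    group term; continuous component: Gaussian model of log-expression
    among detecting cells, LRT for the group term.  Both condition on the
    cellular detection rate (fraction of genes detected per cell) unless
    ``adjust_cdr`` is off — library-depth differences otherwise masquerade
    as differential detection.  The two chi-squares are summed (df 2, or 1
    when one component is degenerate) and BH-adjusted across genes.  A gene
    detected in neither group gets p = 1.  Swapping A and B flips the sign
    of the log2 fold change and leaves p-values unchanged.
    """
    cells_a = np.asarray(cells_a)
    cells_b = np.asarray(cells_b)
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError("both groups need at least 3 cells")
    na, nb = float(len(cells_a)), float(len(cells_b))
    idx = np.concatenate([cells_a, cells_b])
    group = np.concatenate([np.ones(len(cells_a)), np.zeros(len(cells_b))])
    y = np.asarray(nm.values[:, idx].todense(), dtype=float).T    # n x G
    detect = (y > 0).astype(float)
    n = len(idx)

    cdr = detect.mean(axis=1)
    cdr = (cdr - cdr.mean()) / (cdr.std() or 1.0)
    base_cols = [np.ones(n)] + ([cdr] if adjust_cdr else [])
    x0 = np.column_stack(base_cols)
    x1 = np.column_stack(base_cols + [group])

    nza = detect[group == 1].sum(axis=0)
    nzb = detect[group == 0].sum(axis=0)
    det_ok = ~(((nza == 0) & (nzb == 0)) | ((nza == na) & (nzb == nb)))
    g_det = np.zeros(nm.n_genes)
    if det_ok.any():
        ll1 = _batched_logistic_loglik(x1, detect[:, det_ok])
        ll0 = _batched_logistic_loglik(x0, detect[:, det_ok])
        g_det[det_ok] = np.maximum(2.0 * (ll1 - ll0), 0.0)

    # continuous part: detected cells only, via masked weighted regression
    n_det = detect.sum(axis=0)
    cont_ok = (nza >= 2) & (nzb >= 2) & (n_det > x1.shape[1])
    g_cont = np.zeros(nm.n_genes)
    if cont_ok.any():
        rss1 = _masked_wls_rss(x1, y[:, cont_ok], detect[:, cont_ok])
        rss0 = _masked_wls_rss(x0, y[:, cont_ok], detect[:, cont_ok])
        ok_rss = rss1 > 1e-12
        g_sub = np.zeros(rss1.shape)
        g_sub[ok_rss] = n_det[cont_ok][ok_rss] * np.log(rss0[ok_rss] / rss1[ok_rss])
        g_cont[cont_ok] = np.maximum(g_sub, 0.0)
        cont_ok = cont_ok.copy()
        cont_ok[np.flatnonzero(cont_ok)[~ok_rss]] = False

    df = det_ok.astype(int) + cont_ok.astype(int)
    g_total = g_det + g_cont
    pval = np.ones(nm.n_genes)
    testable = df > 0
    pval[testable] = chi2.sf(g_total[testable], df[testable])

    log2fc = (y[group == 1].mean(axis=0) - y[group == 0].mean(axis=0)) / LN2
    padj = np.ones_like(pval)
    if testable.any():
        padj[testable] = multipletests(pval[testable], method="fdr_bh")[1]
    padj = np.maximum(padj, pval)

    return DEResult(pd.DataFrame({
        "gene": nm.genes,
        "log2fc": log2fc,
        "rate_a": nza / na,
        "rate_b": nzb / nb,
        "pval": pval,
        "padj": padj,
    }))


def find_de_genes(
    de: DEResult,
    min_abs_log2fc: float = 0.5,
    max_adj_p: float = 0.01,
    min_rate_diff: float = 0.1,
) -> list[str]:
    """Genes passing all three thresholds: effect size, FDR, detection-rate gap."""
    t = de.table
    hit = (
        (t["log2fc"].abs() >= min_abs_log2fc)
        & (t["padj"] <= max_adj_p)
        & ((t["rate_a"] - t["rate_b"]).abs() >= min_rate_diff)
    )
    return t.loc[hit, "gene"].tolist()


# ---------------------------------------------------------------------------
# Doublet and low-quality cluster rules
# ---------------------------------------------------------------------------

def _cluster_mean_expression(nm: NormalizedMatrix, clusters: list[int],
                             assign: ClusterAssignment) -> np.ndarray:
    """genes x clusters mean of log-normalized values."""
    cols = []
    for c in clusters:
        idx = assign.cluster_cells(c)
        cols.append(np.asarray(nm.values[:, idx].mean(axis=1)).ravel())
    return np.column_stack(cols)


def marker_score_matrix(
    nm: NormalizedMatrix, assign: ClusterAssignment,
    markers: dict[str, set[str]], clusters: list[int] | None = None,
) -> pd.DataFrame:
    """cluster x class matrix of mean marker expression, z-scaled across clusters."""
    if clusters is None:
        clusters = assign.kept_clusters()
    gene_pos = {g: i for i, g in enumerate(nm.genes)}
    mean_expr = _cluster_mean_expression(nm, clusters, assign)  # genes x K
    # z-scale each gene across clusters so "high" is comparable between classes
    mu = mean_expr.mean(axis=1, keepdims=True)
    sd = mean_expr.std(axis=1, keepdims=True)
    z = np.divide(mean_expr - mu, sd, out=np.zeros_like(mean_expr), where=sd > 0)
    out = {}
    for cls, genes in markers.items():
        rows = [gene_pos[g] for g in genes if g in gene_pos]
        missing = [g for g in genes if g not in gene_pos]
        if missing:
            warnings.warn(f"class {cls}: {len(missing)} marker genes absent", stacklevel=2)
        out[cls] = z[rows].mean(axis=0) if rows else np.full(len(clusters), np.nan)
    return pd.DataFrame(out, index=pd.Index(clusters, name="cluster"))


def flag_doublet_clusters(
    m: CountMatrix,
    nm: NormalizedMatrix,
    assign: ClusterAssignment,
    markers: dict[str, set[str]],
    umi_fold: float = 1.5,
    score_threshold: float = 0.5,
    arms: tuple = ("coexpression", "umi"),
    enrich_fold: float = 2.0,
) -> ClusterAssignment:
    """Flag clusters bearing the doublet signature; cells keep their row, status changes.

    Rule arms (individually selectable):
    ``coexpression``      marker score above ``score_threshold`` for >= 2 classes;
    ``no_unique_marker``  no gene enriched >= ``enrich_fold`` over every other cluster;
    ``umi``               median UMI above ``umi_fold`` x the median of
                          same-class cluster medians (skipped for
                          single-cluster classes).
    Arms are OR-combined; the default pairing (marker co-expression, UMI
    load) matches the inflated-content signature of droplet doublets.
    """
    out = assign.copy()
    clusters = out.kept_clusters()
    if not clusters:
        return out
    scores = marker_score_matrix(nm, out, markers, clusters)
    top_class = scores.idxmax(axis=1)
    umi = m.umis_per_cell()
    median_umi = {c: float(np.median(umi[out.cluster_cells(c)])) for c in clusters}
    mean_expr = None
    if "no_unique_marker" in arms:
        mean_expr = np.expm1(_cluster_mean_expression(nm, clusters, out))

    flagged: dict[int, list[str]] = {}
    for j, c in enumerate(clusters):
        hit = []
        if "coexpression" in arms:
            row = scores.loc[c].to_numpy(dtype=float)
            if np.sum(row > score_threshold) >= 2:
                hit.append("coexpression")
        if "no_unique_marker" in arms and len(clusters) > 1:
            others = np.delete(mean_expr, j, axis=1).max(axis=1)
            enriched = mean_expr[:, j] >= enrich_fold * np.maximum(others, 1e-9)
            if not enriched.any():
                hit.append("no_unique_marker")
        if "umi" in arms:
            same = [d for d in clusters if d != c and top_class[d] == top_class[c]]
            if same:  # single-cluster classes skip the UMI arm
                ref = float(np.median([median_umi[d] for d in same]))
                if median_umi[c] > umi_fold * ref:
                    hit.append("umi")
        if hit:
            flagged[c] = hit
    for c in flagged:
        out.status[c] = "doublet"
    out.doublet_log = flagged
    return out


def flag_low_quality_clusters(
    m: CountMatrix,
    nm: NormalizedMatrix,
    assign: ClusterAssignment,
    housekeeping: set[str],
    n_mads: float = 2.0,
    min_rel_drop: float = 0.1,
) -> ClusterAssignment:
    """Flag clusters with outlying low complexity or housekeeping expression.

    A cluster is low quality when its median genes-per-cell OR its mean
    housekeeping expression falls below the across-cluster median minus
    ``n_mads`` scaled MADs — and by at least ``min_rel_drop`` of the median,
    so sampling jitter among healthy clusters (where the MAD itself is
    tiny) cannot trip the rule.  Fewer than 3 kept clusters: nothing is
    flagged.
    """
    if not housekeeping:
        raise ValueError("housekeeping gene set is empty")
    out = assign.copy()
    clusters = out.kept_clusters()
    if len(clusters) < 3:
        warnings.warn("fewer than 3 clusters; low-quality rule skipped", stacklevel=2)
        return out
    gpc = m.genes_per_cell()
    complexity = np.array([np.median(gpc[out.cluster_cells(c)]) for c in clusters], float)
    gene_pos = {g: i for i, g in enumerate(nm.genes)}
    hk_rows = [gene_pos[g] for g in housekeeping if g in gene_pos]
    if not hk_rows:
        raise ValueError("no housekeeping gene found in the matrix")
    hk = np.array([
        float(nm.values[hk_rows][:, out.cluster_cells(c)].mean()) for c in clusters
    ])

    def low(v: np.ndarray) -> np.ndarray:
        med = np.median(v)
        mad = median_abs_deviation(v, scale="normal")
        return (v < med - n_mads * mad) & (v < (1 - min_rel_drop) * med)

    bad = low(complexity) | low(hk)
    for c, b in zip(clusters, bad):
        if b:
            out.status[c] = "low_quality"
    return out


# ---------------------------------------------------------------------------
# Iterative sibling merge
# ---------------------------------------------------------------------------

def _sibling_leaf_pairs(tree) -> list[tuple[str, str, float]]:
    """Leaf pairs that are children of a common parent, by ascending height."""
    pairs = []
    for node in tree.internal_nodes():
        kids = node.children
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            pairs.append((kids[0].name, kids[1].name, node.height))
    return sorted(pairs, key=lambda p: (p[2], p[0], p[1]))


def merge_sibling_clusters(
    nm: NormalizedMatrix,
    assign: ClusterAssignment,
    de_thresholds: dict | None = None,
    gene_mask: np.ndarray | None = None,
    max_merges: int | None = None,
    min_de_genes: int = 5,
) -> ClusterAssignment:
    """Merge dendrogram-sibling clusters with no DE genes until stable.

    Sibling leaf pairs are visited by ascending parent height; when
    :func:`find_de_genes` returns fewer than ``min_de_genes`` hits for a
    pair, the larger id is merged into the smaller and the dendrogram is
    rebuilt.  The floor above zero absorbs the handful of extreme-looking
    genes that post-selection inference produces between noise splits of
    one population (the split direction was chosen by clustering the same
    cells); genuinely distinct types differ in far more genes.  Terminates after at most K-1 merges.  The merge log
    (pair, n DE genes, action) is attached to the returned assignment.
    """
    from .trees import cluster_profiles, linkage_tree

    thr = dict(de_thresholds or {})
    min_de_genes = int(thr.pop("de_min_genes", min_de_genes))
    out = assign.copy()
    log = []
    n_start = len(out.kept_clusters())
    merges_left = (n_start - 1) if max_merges is None else max_merges
    while merges_left > 0:
        kept = out.kept_clusters()
        if len(kept) < 2:
            break
        profiles = cluster_profiles(nm, out, gene_mask=gene_mask)
        tree = linkage_tree(profiles)
        merged_this_pass = False
        for name_a, name_b, height in _sibling_leaf_pairs(tree):
            a, b = int(name_a), int(name_b)
            de = hurdle_de_test(nm, out.cluster_cells(a), out.cluster_cells(b))
            hits = find_de_genes(de, **thr)
            if len(hits) >= min_de_genes:
                log.append((a, b, len(hits), "kept"))
                continue
            src, dst = max(a, b), min(a, b)
            out.status[src] = "merged"
            out.merged_into[src] = dst
            out.labels = np.where(out.labels == src, dst, out.labels)
            log.append((src, dst, 0, "merged"))
            merges_left -= 1
            merged_this_pass = True
            break  # dendrogram changed; rebuild
        if not merged_this_pass:
            break
    out.merge_log = log
    return out
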