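"""PCA, Tracy-Widom significant-PC estimation, SNN graph and community clustering.

The number of meaningful principal components is decided by sequential
testing of the leading sample-covariance eigenvalues against the
Tracy-Widom (GOE/TW1) null for white Wishart matrices: each eigenvalue is
normalized against the remaining spectrum, centered and scaled with the
Marchenko-Pastur edge constants for the effective dimensions, and declared
significant while the statistic exceeds the TW1 upper-alpha quantile.  The
TW1 quantile itself is computed numerically from the Painleve II
representation of the distribution (Hastings-McLeod solution), not taken
from a lookup table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.integrate import cumulative_trapezoid, solve_bvp
from scipy.special import airy
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.extmath import randomized_svd

from .preprocess import NormalizedMatrix


# ---------------------------------------------------------------------------
# Tracy-Widom (beta = 1) distribution via Painleve II
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _tw1_cdf_table() -> tuple[np.ndarray, np.ndarray]:
    """Tabulate the TW1 CDF on a grid from the Painleve II representation.

    The Hastings-McLeod solution of q'' = x q + 2 q^3 (q ~ Ai(x) as
    x -> +inf, q ~ sqrt(-x/2) as x -> -inf) is obtained as a two-point
    boundary-value problem — forward shooting is numerically unstable —
    and the CDF assembled as
    F2(s) = exp(-int_s^inf (x - s) q^2 dx),
    F1(s) = sqrt(F2(s)) * exp(-1/2 int_s^inf q dx).
    """
    x_lo, x_hi = -13.0, 8.0
    ai_hi = float(airy(x_hi)[0])
    hm_left = np.sqrt(-x_lo / 2.0) * (1.0 + 1.0 / (8.0 * x_lo**3))

    def rhs(x, y):
        return np.vstack([y[1], x * y[0] + 2.0 * y[0] ** 3])

    def bc(ya, yb):
        return np.array([ya[0] - hm_left, yb[0] - ai_hi])

    xm = np.linspace(x_lo, x_hi, 2001)
    guess = np.where(xm < 0, np.sqrt(np.maximum(-xm, 0) / 2.0),
                     airy(np.maximum(xm, 0))[0])
    sol = solve_bvp(rhs, bc, xm, np.vstack([guess, np.gradient(guess, xm)]),
                    tol=1e-10, max_nodes=200_000)
    if sol.status != 0:
        raise RuntimeError(f"Painleve II BVP failed: {sol.message}")
    xs = np.linspace(x_lo, x_hi, 6001)
    q = sol.sol(xs)[0]

    def tail_integral(f: np.ndarray) -> np.ndarray:
        c = cumulative_trapezoid(f, xs, initial=0.0)
        return c[-1] - c

    A = tail_integral(q)              # int_s q dx
    B = tail_integral(q**2)           # int_s q^2 dx
    C = tail_integral(xs * q**2)      # int_s x q^2 dx
    log_f2 = -(C - xs * B)
    f1 = np.exp(0.5 * log_f2 - 0.5 * A)
    return xs, np.clip(f1, 0.0, 1.0)


def tw1_cdf(s: float | np.ndarray) -> np.ndarray:
    """CDF of the Tracy-Widom distribution for the Gaussian orthogonal ensemble."""
    xs, f1 = _tw1_cdf_table()
    return np.interp(s, xs, f1)


def tw1_quantile(p: float) -> float:
    """Quantile of TW1 (e.g. ``tw1_quantile(0.95)`` is the alpha=0.05 critical value)."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    xs, f1 = _tw1_cdf_table()
    return float(np.interp(p, f1, xs))


def _mp_edge_constants(n: int, m: int) -> tuple[float, float]:
    """Centering/scaling of the largest eigenvalue of an n x m white Wishart."""
    a, b = np.sqrt(n - 1), np.sqrt(m)
    mu = (a + b) ** 2
    sigma = (a + b) * (1.0 / a + 1.0 / b) ** (1.0 / 3.0)
    return mu, sigma


def count_significant_pcs_tw(
    eigenvalues,
    n_cells: int,
    n_genes: int,
    alpha: float = 0.05,
    trace: float | None = None,
) -> int:
    """Sequential Tracy-Widom test for the number of significant PCs.

    ``eigenvalues`` are the descending sample-covariance eigenvalues of
    unit-variance (scaled) data; ``trace`` is the total variance (defaults
    to ``n_genes``, exact for z-scaled genes).  At step i the top remaining
    eigenvalue is rescaled by the remaining average noise variance, mapped
    to Wishart scale with effective dimensions (n_cells - i + 1, n_genes),
    and compared with the TW1 upper-``alpha`` quantile.  Testing stops at
    the first non-significant eigenvalue.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < 2:
        return 0
    if np.any(np.diff(ev) > 1e-9):
        raise ValueError("eigenvalues must be sorted in descending order")
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must be in (0, 0.5]")
    crit = tw1_quantile(1.0 - alpha)
    total = float(trace) if trace is not None else float(n_genes)
    consumed = 0.0
    n_sig = 0
    for i, lam in enumerate(ev):
        n_eff = n_cells - i
        if n_eff < 3:
            break
        remaining = total - consumed
        if remaining <= 0:
            break
        noise_var = remaining / n_genes
        ell = (n_eff - 1) * lam / noise_var
        mu, sigma = _mp_edge_constants(n_eff, n_genes)
        stat = (ell - mu) / sigma
        if stat > crit:
            n_sig += 1
            consumed += lam
        else:
            break
    return n_sig


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCModel:
    """Truncated PCA of the scaled HVG matrix (cells as observations)."""

    loadings: np.ndarray       # genes x k
    scores: np.ndarray         # cells x k
    eigenvalues: np.ndarray    # descending, covariance scale
    n_significant: int = 0


def run_pca(nm: NormalizedMatrix, k: int = 50, seed: int = 0) -> PCModel:
    """Top-k PCA of the scaled HVG submatrix via seeded randomized SVD."""
    if not nm.is_scaled():
        raise ValueError("scale_genes must run before PCA")
    x = nm.scaled.T                                   # cells x hvg, gene-centered
    kmax = min(x.shape[0] - 1, x.shape[1])
    if k > kmax:
        warnings.warn(f"k={k} capped to {kmax}", stacklevel=2)
        k = kmax
    u, s, vt = randomized_svd(x, n_components=k, random_state=seed, n_iter=7)
    eig = s**2 / max(x.shape[0] - 1, 1)
    return PCModel(loadings=vt.T, scores=u * s, eigenvalues=eig)


# ---------------------------------------------------------------------------
# kNN / SNN graph and clustering
# ---------------------------------------------------------------------------

def build_knn_graph(
    scores: np.ndarray,
    n_pcs: int,
    k_neighbors: int = 20,
    weighting: str = "snn",
    prune: float = 1.0 / 15.0,
) -> ig.Graph:
    """Euclidean kNN graph in PC space with shared-nearest-neighbor weights.

    Edge weight is the Jaccard overlap of the two endpoints' neighbor sets
    (self included); overlaps at or below ``prune`` are dropped.  With
    ``weighting='knn'`` plain unit-weight kNN edges are returned.
    """
    if n_pcs <= 0:
        raise ValueError(
            "n_pcs must be >= 1; if the Tracy-Widom step returned 0, apply a "
            "floor (PipelineConfig.min_significant_pcs) before building the graph"
        )
    if k_neighbors < 2:
        raise ValueError("k_neighbors must be >= 2")
    x = np.asarray(scores)[:, :n_pcs]
    n = x.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)                 # includes self in column 0
    rows = np.repeat(np.arange(n), k + 1)
    adj = sp.csr_matrix(
        (np.ones(n * (k + 1), dtype=np.int32), (rows, idx.ravel())), shape=(n, n)
    )
    mutual = adj.maximum(adj.T)
    if weighting == "knn":
        w = sp.triu(mutual, k=1).tocoo()
        g = ig.Graph(n=n, edges=list(zip(w.row.tolist(), w.col.tolist())))
        g.es["weight"] = [1.0] * g.ecount()
        return g
    shared = (adj @ adj.T).multiply(mutual)   # only candidate pairs
    shared = sp.triu(shared, k=1).tocoo()
    jac = shared.data / (2.0 * (k + 1) - shared.data)
    keep = jac > prune
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jac[keep].tolist()
    return g


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels plus per-cluster QC status.

    ``status[c]`` is one of ``kept``, ``doublet``, ``low_quality``,
    ``merged``; merged clusters record their target in ``merged_into``.
    """

    cells: list[str]
    labels: np.ndarray
    resolution: float
    status: dict = field(default_factory=dict)
    merged_into: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.cells):
            raise ValueError("one label per cell required")
        for c in self.cluster_ids():
            self.status.setdefault(int(c), "kept")

    def cluster_ids(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.labels))

    def kept_clusters(self) -> list[int]:
        return [c for c in self.cluster_ids() if self.status.get(c) == "kept"]

    def cluster_cells(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)

    def resolve(self, c: int) -> int:
        """Follow merge pointers to the surviving cluster id."""
        seen = set()
        while self.status.get(c) == "merged":
            if c in seen:
                raise RuntimeError("merge cycle")
            seen.add(c)
            c = self.merged_into[c]
        return c

    def effective_labels(self) -> np.ndarray:
        """Labels with merged clusters mapped onto their surviving targets."""
        mapping = {c: self.resolve(c) for c in self.cluster_ids()}
        return np.array([mapping[int(l)] for l in self.labels])

    def cell_status(self) -> np.ndarray:
        st = {c: self.status.get(c, "kept") for c in self.cluster_ids()}
        return np.array([st[int(l)] for l in self.labels])

    def kept_cell_mask(self) -> np.ndarray:
        eff = self.effective_labels()
        return np.array([self.status.get(int(c), "kept") == "kept" for c in eff])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "barcode": self.cells,
            "cluster": self.effective_labels(),
            "status": self.cell_status(),
        })

    def copy(self) -> "ClusterAssignment":
        return ClusterAssignment(
            cells=list(self.cells), labels=self.labels.copy(),
            resolution=self.resolution, status=dict(self.status),
            merged_into=dict(self.merged_into),
        )


def cluster_communities(
    graph: ig.Graph,
    resolution: float = 0.8,
    seed: int = 0,
    cells: list[str] | None = None,
) -> ClusterAssignment:
    """Leiden modularity communities; labels 0..K-1 by descending cluster size."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=graph.es["weight"] if graph.ecount() else None,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=5,
    )
    raw = np.array(part.membership)
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[r] for r in raw])
    if cells is None:
        cells = [f"v{i}" for i in range(graph.vcount())]
    return ClusterAssignment(cells=list(cells), labels=labels, resolution=resolution)


def embed_umap(scores: np.ndarray, n_pcs: int, seed: int = 0) -> np.ndarray:
    """Optional 2-D UMAP layout of the significant-PC space (visualization only)."""
    try:
        import umap
    except ImportError as exc:
        raise ImportError("embed_umap needs the optional umap-learn dependency") from exc
    x = np.asarray(scores)[:, :max(n_pcs, 2)]
    reducer = umap.UMAP(n_components=2, random_state=seed)
    return np.asarray(reducer.fit_transform(x), dtype=float)
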