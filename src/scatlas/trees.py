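"""Dendrograms over cluster profiles with bootstrap support values.

Two kinds of support are produced.  Multiscale bootstrap resampling
rebuilds the tree from gene resamples of several sizes (50-140% of the
original), records per-edge recovery frequencies, and extrapolates them to
an approximately-unbiased (AU) support via the signed-distance/curvature
model: Phi^-1(1 - BP(r)) = d sqrt(r) + c / sqrt(r), AU = 1 - Phi(d - c).
Repeated 80%-cells / 80%-genes rebuilds summarized by majority-rule
consensus give frequency supports for pooled cross-dataset trees.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .embed import ClusterAssignment
from .preprocess import NormalizedMatrix


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    height: float = 0.0
    name: str | None = None
    support: float | None = None
    children: list = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out


@dataclass
class SupportTree:
    """Rooted tree over named leaves with heights and optional [0, 100] supports."""

    root: TreeNode

    def leaves(self) -> list[str]:
        return self.root.leaf_names()

    def _walk(self, node=None):
        node = node or self.root
        yield node
        for c in node.children:
            yield from self._walk(c)

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self._walk() if not n.is_leaf()]

    def clades(self, trivial: bool = False) -> set[frozenset]:
        """Leaf sets under internal nodes (excluding root and, optionally, leaves)."""
        full = frozenset(self.leaves())
        out = set()
        for n in self.internal_nodes():
            cl = frozenset(n.leaf_names())
            if cl != full:
                out.add(cl)
        if trivial:
            out |= {frozenset([l]) for l in full}
        return out

    def clade_map(self) -> dict[frozenset, TreeNode]:
        return {frozenset(n.leaf_names()): n for n in self.internal_nodes()}

    def support_table(self) -> pd.DataFrame:
        rows = [
            {"clade": "|".join(sorted(n.leaf_names())), "height": n.height,
             "support": n.support}
            for n in self.internal_nodes()
        ]
        return pd.DataFrame(rows)

    def newick(self) -> str:
        def fmt(node: TreeNode, parent_height: float | None) -> str:
            if node.is_leaf():
                body = _quote(node.name)
            else:
                inner = ",".join(fmt(c, node.height) for c in node.children)
                label = "" if node.support is None else f"{node.support:g}"
                body = f"({inner}){label}"
            if parent_height is None:
                return body
            return f"{body}:{max(parent_height - node.height, 0.0):g}"

        return fmt(self.root, None) + ";"


def _quote(name: str) -> str:
    if re.search(r"[\s()\[\]{},;:']", name):
        return "'" + name.replace("'", "''") + "'"
    return name


# ---------------------------------------------------------------------------
# Profiles and linkage
# ---------------------------------------------------------------------------

def cluster_profiles(
    nm: NormalizedMatrix,
    assign: ClusterAssignment,
    gene_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Kept-cluster centroids (mean scaled HVG expression), clusters x genes."""
    if not nm.is_scaled():
        raise ValueError("cluster_profiles needs the scaled HVG matrix")
    hvg_genes = nm.hvg_genes
    mat = nm.scaled
    if gene_mask is not None:
        gene_mask = np.asarray(gene_mask, dtype=bool)
        mat = mat[gene_mask]
        hvg_genes = [g for g, m in zip(hvg_genes, gene_mask) if m]
    rows, names = [], []
    for c in assign.kept_clusters():
        idx = assign.cluster_cells(c)
        if idx.size == 0:
            warnings.warn(f"cluster {c} is empty; excluded from profiles", stacklevel=2)
            continue
        rows.append(mat[:, idx].mean(axis=1))
        names.append(str(c))
    return pd.DataFrame(rows, index=pd.Index(names, name="cluster"), columns=hvg_genes)


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance; constant rows fall back to distance 1."""
    sd = x.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("constant profile: correlation undefined, using distance 1",
                      stacklevel=3)
        d = np.ones((x.shape[0], x.shape[0])) - np.eye(x.shape[0])
        ok = sd > 0
        if ok.sum() >= 2:
            sub = squareform(pdist(x[ok], metric="correlation"))
            d[np.ix_(ok, ok)] = sub
        return squareform(d, checks=False)
    return pdist(x, metric="correlation")


def linkage_tree(
    profiles: pd.DataFrame,
    metric: str = "correlation",
    method: str = "average",
) -> SupportTree:
    """Agglomerative tree on profiles; 1 - Pearson / average linkage by default.

    Input rows are pre-sorted by leaf name so equal-distance ties resolve
    by name order, making the topology independent of input row order.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    profiles = profiles.sort_index(kind="stable")
    x = profiles.to_numpy(dtype=float)
    names = [str(i) for i in profiles.index]
    if metric == "correlation":
        dist = _correlation_distance(x)
    elif metric == "spearman":
        rank = pd.DataFrame(x.T).rank().to_numpy().T
        dist = _correlation_distance(rank)
    else:
        dist = pdist(x, metric=metric)
    z = linkage(dist, method=method)
    nodes = [TreeNode(height=0.0, name=n) for n in names]
    for a, b, h, _ in z:
        nodes.append(TreeNode(height=float(h), children=[nodes[int(a)], nodes[int(b)]]))
    return SupportTree(root=nodes[-1])


# ---------------------------------------------------------------------------
# Multiscale bootstrap (AU) support
# ---------------------------------------------------------------------------

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))


def _fit_au(bp_by_scale: dict[float, float], n_boot: int) -> float:
    """AU value from per-scale bootstrap probabilities by WLS extrapolation."""
    scales = np.array(sorted(bp_by_scale))
    bp = np.array([bp_by_scale[r] for r in scales])
    if np.all(bp >= 1.0):
        return 1.0
    if np.all(bp <= 0.0):
        return 0.0
    eps = 0.5 / n_boot
    bpc = np.clip(bp, eps, 1 - eps)
    z = norm.ppf(1.0 - bpc)
    # scale sigma = 1/sqrt(r); model z(sigma) = d*sigma + c/sigma, i.e.
    # z = d/sqrt(r) + c*sqrt(r); AU = 1 - Phi(d - c)
    x_dist, x_curv = 1.0 / np.sqrt(scales), np.sqrt(scales)
    w = n_boot * norm.pdf(z) ** 2 / (bpc * (1 - bpc))
    xmat = np.column_stack([x_dist, x_curv])
    wm = xmat * w[:, None]
    try:
        coef = np.linalg.solve(xmat.T @ wm, wm.T @ z)
    except np.linalg.LinAlgError:
        return float(np.mean(bpc))
    d, c = coef
    return float(norm.sf(d - c))


def multiscale_bootstrap_support(
    nm: NormalizedMatrix,
    assign: ClusterAssignment,
    gene_mask: np.ndarray | None = None,
    scales: tuple = DEFAULT_SCALES,
    n_boot: int = 100,
    seed: int = 0,
    unit: str = "genes",
) -> SupportTree:
    """Linkage tree with AU supports from multiscale bootstrap resampling.

    For each scale r the resampling unit (``genes`` by default, ``cells``
    optional) is drawn with replacement to ceil(r x size), the tree is
    rebuilt, and per-edge recovery frequencies BP(r) are recorded; supports
    are round(100 x AU), clamped to [0, 100].
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not (min(scales) < 1.0 <= max(scales) + 1e-9):
        warnings.warn("scales should span values below and above 1", stacklevel=2)
    rng = np.random.default_rng(seed)
    profiles = cluster_profiles(nm, assign, gene_mask=gene_mask)
    base = linkage_tree(profiles)
    target = base.clades()
    counts = {cl: {float(r): 0 for r in scales} for cl in target}
    x = profiles.to_numpy(dtype=float)
    n_genes = x.shape[1]

    if unit == "cells":
        kept = assign.kept_clusters()
        cell_idx = {c: assign.cluster_cells(c) for c in kept}
        all_cells = np.concatenate([cell_idx[c] for c in kept])
        cell_cluster = np.concatenate([np.full(len(cell_idx[c]), c) for c in kept])
        mat = nm.scaled if gene_mask is None else nm.scaled[np.asarray(gene_mask, bool)]

    for r in scales:
        r = float(r)
        for _ in range(n_boot):
            if unit == "genes":
                cols = rng.integers(0, n_genes, int(np.ceil(r * n_genes)))
                prof_b = pd.DataFrame(x[:, cols], index=profiles.index)
            elif unit == "cells":
                take = rng.integers(0, len(all_cells), int(np.ceil(r * len(all_cells))))
                rows, names = [], []
                for c in kept:
                    sel = all_cells[take][cell_cluster[take] == c]
                    if sel.size == 0:
                        continue
                    rows.append(mat[:, sel].mean(axis=1))
                    names.append(str(c))
                if len(rows) < 2:
                    continue
                prof_b = pd.DataFrame(rows, index=names)
            else:
                raise ValueError("unit must be 'genes' or 'cells'")
            tree_b = linkage_tree(prof_b)
            found = tree_b.clades()
            for cl in target:
                if cl in found:
                    counts[cl][r] += 1

    for clade, node in base.clade_map().items():
        if clade not in counts:       # root
            continue
        bp = {r: counts[clade][r] / n_boot for r in counts[clade]}
        au = _fit_au(bp, n_boot)
        node.support = float(np.clip(round(100 * au), 0, 100))
    return base


# ---------------------------------------------------------------------------
# Resampled builds and majority-rule consensus
# ---------------------------------------------------------------------------

def resampled_builds(
    nm: NormalizedMatrix,
    assign: ClusterAssignment,
    n_builds: int = 100,
    cell_frac: float = 0.8,
    gene_frac: float = 0.8,
    seed: int = 0,
    gene_mask: np.ndarray | None = None,
) -> list[SupportTree]:
    """Trees from repeated subsampling: ``cell_frac`` of cells and
    ``gene_frac`` of HVGs, each without replacement."""
    if n_builds < 2:
        raise ValueError("n_builds must be >= 2")
    rng = np.random.default_rng(seed)
    mat = nm.scaled if gene_mask is None else nm.scaled[np.asarray(gene_mask, bool)]
    n_genes, n_cells = mat.shape
    kept = assign.kept_clusters()
    cell_idx = {c: assign.cluster_cells(c) for c in kept}
    trees = []
    for _ in range(n_builds):
        genes = rng.choice(n_genes, size=max(int(gene_frac * n_genes), 2), replace=False)
        cells = rng.choice(n_cells, size=max(int(cell_frac * n_cells), 1), replace=False)
        in_cells = np.zeros(n_cells, bool)
        in_cells[cells] = True
        rows, names = [], []
        for c in kept:
            sel = cell_idx[c][in_cells[cell_idx[c]]]
            if sel.size == 0:
                warnings.warn(f"cluster {c} emptied by resampling; leaf dropped",
                              stacklevel=2)
                continue
            rows.append(mat[np.ix_(genes, sel)].mean(axis=1))
            names.append(str(c))
        if len(rows) >= 2:
            trees.append(linkage_tree(pd.DataFrame(rows, index=names)))
    return trees


def consensus_tree(trees: list[SupportTree], min_frac: float = 0.5) -> SupportTree:
    """Majority-rule consensus: clades in > ``min_frac`` of trees, support =
    percent occurrence; unresolved regions collapse to polytomies.

    Trees with differing leaf sets are an error unless the difference came
    from dropped leaves, in which case the consensus is restricted to the
    common leaf set (with a warning).
    """
    if not trees:
        raise ValueError("no trees given")
    leaf_sets = [frozenset(t.leaves()) for t in trees]
    common = frozenset.intersection(*leaf_sets)
    if not common:
        raise ValueError("trees share no leaves")
    if any(ls != common for ls in leaf_sets):
        warnings.warn("inconsistent leaf sets; consensus restricted to common leaves",
                      stacklevel=2)
    n = len(trees)
    counts: dict[frozenset, int] = {}
    heights: dict[frozenset, list[float]] = {}
    for t in trees:
        for clade, node in t.clade_map().items():
            cl = frozenset(clade & common)
            if len(cl) < 2 or cl == common:
                continue
            counts[cl] = counts.get(cl, 0) + 1
            heights.setdefault(cl, []).append(node.height)
    majority = [cl for cl, k in counts.items() if k / n > min_frac]
    majority.sort(key=len)

    root_height = float(np.mean([t.root.height for t in trees]))
    node_of: dict[frozenset, TreeNode] = {
        frozenset([l]): TreeNode(height=0.0, name=l) for l in common
    }
    for cl in majority:
        node_of[cl] = TreeNode(
            height=float(np.mean(heights[cl])),
            support=round(100.0 * counts[cl] / n, 10),
        )
    # attach each node to the smallest strictly-containing majority clade
    full = frozenset(common)
    node_of[full] = TreeNode(height=root_height, support=None)
    order = sorted(node_of, key=len)
    for cl in order:
        if cl == full:
            continue
        parents = [p for p in node_of if len(p) > len(cl) and cl < p]
        parent = min(parents, key=len)
        node_of[parent].children.append(node_of[cl])
    for nd in node_of.values():
        nd.children.sort(key=lambda k: sorted(k.leaf_names())[0])
        if nd.children:
            top = max(c.height for c in nd.children)
            if nd.height < top:   # keep heights monotone toward the root
                nd.height = top
    return SupportTree(root=node_of[full])


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: SupportTree, path) -> "Path":
    """Serialize with supports as internal labels and heights as branch lengths."""
    from pathlib import Path

    if tree.root is None or (tree.root.is_leaf() and tree.root.name is None):
        raise ValueError("empty tree")
    p = Path(path)
    p.write_text(tree.newick() + "\n")
    return p


def read_newick(source) -> SupportTree:
    """Parse a newick string or file written by :func:`write_newick`."""
    from pathlib import Path

    text = source
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and not source.rstrip().endswith(";")):
        text = Path(source).read_text()
    text = text.strip().rstrip(";")
    pos = 0

    def parse() -> tuple[TreeNode, float | None]:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                child, length = parse()
                child._blen = length
                node.children.append(child)
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
            label = _token()
            if label:
                node.support = float(label)
        else:
            node.name = _token()
        length = None
        if pos < len(text) and text[pos] == ":":
            pos += 1
            length = float(_token())
        return node, length

    def _token() -> str:
        nonlocal pos
        if pos < len(text) and text[pos] == "'":
            pos += 1
            out = []
            while True:
                if text[pos] == "'" and pos + 1 < len(text) and text[pos + 1] == "'":
                    out.append("'")
                    pos += 2
                elif text[pos] == "'":
                    pos += 1
                    break
                else:
                    out.append(text[pos])
                    pos += 1
            return "".join(out)
        m = re.match(r"[^(),:;]*", text[pos:])
        tok = m.group(0)
        pos += len(tok)
        return tok

    root, _ = parse()

    def set_heights(node: TreeNode) -> float:
        if node.is_leaf():
            node.height = 0.0
            return 0.0
        hs = []
        for c in node.children:
            sub = set_heights(c)
            hs.append(sub + (getattr(c, "_blen", None) or 0.0))
        node.height = max(hs)
        return node.height

    set_heights(root)
    return SupportTree(root=root)
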