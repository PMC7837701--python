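"""Count-matrix container, standard-format readers/writers, and pipeline configuration.

The on-disk convention is the 10x triplet layout: ``matrix.mtx`` (Matrix
Market coordinate, genes x cells, 1-based) plus ``features.tsv`` and
``barcodes.tsv`` registries.  Marker tables, homolog tables and cluster
tables are plain TSV.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class IntegrityError(ValueError):
    """File contents violate an internal-consistency invariant."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse gene x cell UMI count matrix with gene and barcode registries.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes on rows, cells on columns.
    genes, cells
        Unique, ordered identifier lists matching the matrix dimensions.
    meta
        Optional per-cell annotation (dataset id, age tag, species tag, ...),
        indexed by barcode.
    """

    counts: sp.csr_matrix
    genes: list[str]
    cells: list[str]
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = list(self.genes)
        self.cells = list(self.cells)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise IntegrityError(
                f"count matrix is {self.counts.shape} but registries have "
                f"{len(self.genes)} genes and {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise IntegrityError("duplicate gene identifiers")
        if len(set(self.cells)) != len(self.cells):
            raise IntegrityError("duplicate cell barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise IntegrityError("negative counts")
        data = self.counts.data
        if data.size and not np.allclose(data, np.round(data)):
            raise IntegrityError("non-integral counts")
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.cells, name="barcode"))
        else:
            self.meta = self.meta.loc[self.cells]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0 in each cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def umis_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[:, idx],
            genes=self.genes,
            cells=[self.cells[i] for i in idx],
            meta=self.meta.iloc[idx] if self.meta is not None else None,
        )

    def subset_genes(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[idx, :],
            genes=[self.genes[i] for i in idx],
            cells=self.cells,
            meta=self.meta,
        )


def _open_maybe_gz(base: Path):
    if base.exists():
        return open(base, "rb")
    gz = base.with_name(base.name + ".gz")
    if gz.exists():
        return gzip.open(gz, "rb")
    raise FormatError(f"missing file: {base} (or {base.name}.gz)")


def _read_tsv_registry(dir_path: Path, name: str) -> pd.DataFrame:
    with _open_maybe_gz(dir_path / name) as fh:
        return pd.read_csv(fh, sep="\t", header=None, dtype=str)


def read_counts_mtx(dir_path: str | Path) -> CountMatrix:
    """Read a 10x-style triplet directory (matrix.mtx + features.tsv + barcodes.tsv).

    Both ``integer`` and ``real`` Matrix Market headers are accepted; real
    values are coerced to integers only when they are integral.
    """
    dir_path = Path(dir_path)
    with _open_maybe_gz(dir_path / "matrix.mtx") as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:  # malformed header / triplets
            raise FormatError(f"cannot parse matrix.mtx: {exc}") from exc
    mat = sp.csr_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError("matrix.mtx holds non-integral real values")
    mat.data = np.round(mat.data).astype(np.int64)

    feats = _read_tsv_registry(dir_path, "features.tsv")
    genes = feats.iloc[:, 0].tolist()
    barcodes = _read_tsv_registry(dir_path, "barcodes.tsv").iloc[:, 0].tolist()
    if mat.shape[0] != len(genes) or mat.shape[1] != len(barcodes):
        raise IntegrityError(
            f"matrix is {mat.shape} but features.tsv has {len(genes)} rows "
            f"and barcodes.tsv has {len(barcodes)} rows"
        )
    meta = None
    if feats.shape[1] >= 2:
        meta = None  # display names kept out of per-cell meta
    return CountMatrix(counts=mat, genes=genes, cells=barcodes, meta=meta)


def write_counts_mtx(cm: CountMatrix, dir_path: str | Path) -> Path:
    """Write a CountMatrix in the triplet layout read by :func:`read_counts_mtx`."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), sp.coo_matrix(cm.counts), field="integer")
    pd.Series(cm.genes).to_csv(dir_path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(cm.cells).to_csv(dir_path / "barcodes.tsv", sep="\t", header=False, index=False)
    return dir_path


# ---------------------------------------------------------------------------
# Marker / homolog / cluster tables
# ---------------------------------------------------------------------------

def read_marker_table(path: str | Path) -> dict[str, set[str]]:
    """Read a TSV of (class, gene) rows into a class -> gene-set map.

    Duplicate rows are deduplicated; a gene may appear under several classes
    (ambiguity is resolved downstream by marker scoring).
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"marker table {path} is empty") from None
    df = df.dropna()
    if df.empty:
        raise FormatError(f"marker table {path} is empty")
    if df.shape[1] < 2:
        raise FormatError("marker table needs columns: class, gene")
    out: dict[str, set[str]] = {}
    for cls, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(cls, set()).add(gene)
    return out


def default_markers() -> dict[str, set[str]]:
    """Canonical retinal class markers shipped with the package.

    PR photoreceptors, HC horizontal, BC bipolar, AC amacrine, RGC ganglion
    cells, MG Mueller glia, OL oligodendrocytes.
    """
    path = Path(__file__).parent / "data" / "retina_class_markers.tsv"
    return read_marker_table(path)


def read_homolog_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a TSV of (species, gene, group) rows into per-species gene -> group maps.

    A gene mapped to two distinct groups within one species is an integrity
    error; groups missing from some species are retained here and filtered
    during harmonization.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str).dropna()
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    if df.shape[1] < 3:
        raise FormatError("homolog table needs columns: species, gene, group")
    out: dict[str, dict[str, str]] = {}
    for species, gene, group in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
        smap = out.setdefault(species, {})
        if gene in smap and smap[gene] != group:
            raise IntegrityError(f"{species}:{gene} mapped to both {smap[gene]} and {group}")
        smap[gene] = group
    return out


def write_homolog_table(homologs: dict[str, dict[str, str]], path: str | Path) -> Path:
    rows = [(sp_, g, grp) for sp_, m in homologs.items() for g, grp in m.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    return Path(path)


def write_cluster_table(assign, path: str | Path) -> Path:
    """Write a per-cell cluster table (barcode, cluster, status) as TSV."""
    df = assign.to_frame()
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "cluster": int, "status": str})
    expected = ["barcode", "cluster", "status"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"cluster table must have columns {expected}")
    return df


# ---------------------------------------------------------------------------
# PipelineConfig
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Tunable constants of the atlas pipeline.

    Defaults are the published protocol values: 600-gene cell QC, log
    normalization to 10,000 counts, clustering resolution 0.8, 1.5-fold
    UMI doublet rule, 200-cell per-type cap for pooling, 100 dendrogram
    builds on 80% of cells and 80% of HVGs, and a 10-90% x 10-repeat
    saturation grid.
    """

    min_genes_per_cell: int = 600
    scale_factor: int = 10_000
    n_hvgs: int = 2000
    scale_cap: float = 10.0
    k_neighbors: int = 20
    cluster_resolution: float = 0.8
    tw_alpha: float = 0.05
    min_significant_pcs: int = 5
    max_pcs: int = 50
    doublet_umi_fold: float = 1.5
    de_min_abs_log2fc: float = 0.5
    de_max_adj_p: float = 0.01
    de_min_rate_diff: float = 0.1
    de_min_genes: int = 5
    max_cells_per_type: int = 200
    n_tree_builds: int = 100
    tree_cell_frac: float = 0.8
    tree_gene_frac: float = 0.8
    saturation_fracs: tuple = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))
    saturation_reps: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tree_cell_frac", "tree_gene_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for f in self.saturation_fracs:
            if not 0 < f <= 1:
                raise ValueError(f"saturation fraction {f} outside (0, 1]")
        for name in ("scale_factor", "n_hvgs", "k_neighbors", "max_cells_per_type",
                     "n_tree_builds", "saturation_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")
        if self.cluster_resolution <= 0 or self.doublet_umi_fold <= 0:
            raise ValueError("resolution and doublet_umi_fold must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from JSON or flat ``key=value`` text."""
        text = Path(path).read_text()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise FormatError(f"bad config line: {line!r}")
                k, v = line.split("=", 1)
                raw[k.strip()] = json.loads(v.strip()) if v.strip()[:1] in "[{0123456789.-tfn\"" else v.strip()
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "saturation_fracs" in raw:
            raw["saturation_fracs"] = tuple(raw["saturation_fracs"])
        return cls(**raw)

    def to_json(self, path: str | Path | None = None) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    def with_(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a stable per-stage child seed (< 2**31) from a root seed."""
    import hashlib

    h = hashlib.blake2s(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)
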