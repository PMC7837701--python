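"""Negative-binomial droplet UMI simulator with nested class/type structure.

Generates gene x cell count matrices that emulate the statistical features
the atlas pipeline must cope with: hierarchical identity (classes that
split into types sharing class markers), lognormal library-size variation,
gamma-Poisson (negative binomial) overdispersion, doublets formed by
summing two singlet transcriptomes, developmental intermediates whose mean
profile mixes a precursor and a mature state, and positional gradient
genes within one designated class.  Every cell carries full ground-truth
labels so downstream recovery can be scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix


@dataclass
class ClassSpec:
    """One cell class: its types, marker budget, and relative abundance."""

    name: str
    n_types: int = 2
    n_class_markers: int = 20
    n_type_markers_per_type: int = 30
    weight: float = 1.0


@dataclass
class GroundTruth:
    """Simulator-emitted per-cell truth used by all recovery tests."""

    table: pd.DataFrame  # columns: cell, class_label, type_label, doublet, type_label_2, maturity, mix_weight, pos_x, pos_y, age

    @property
    def class_labels(self) -> np.ndarray:
        return self.table["class_label"].to_numpy()

    @property
    def type_labels(self) -> np.ndarray:
        return self.table["type_label"].to_numpy()

    @property
    def doublet_mask(self) -> np.ndarray:
        return self.table["doublet"].to_numpy(dtype=bool)

    def n_types_planted(self) -> int:
        singlets = self.table[~self.table["doublet"]]
        return singlets["type_label"].nunique()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class AtlasSimSpec:
    """Parameters of one simulated atlas.

    ``base_mean`` is the negative-binomial mean of a background gene in a
    cell of unit depth; markers are multiplied by ``marker_fold`` in the
    class/type that owns them.  ``dispersion`` is the shared NB size
    parameter (variance = mu + mu^2/dispersion); larger values approach
    Poisson.  ``libsize_sigma`` is the SD of the lognormal per-cell depth
    factor.  ``intermediate_frac_by_age`` maps an age tag to the fraction
    of its cells drawn as precursor-mature mixtures; cells are split evenly
    across the listed ages.  ``gradient_genes`` lists (gene_index, axis)
    pairs, axis in {"x", "y", "r"}, applied within ``gradient_class``.
    """

    n_genes: int = 2000
    classes: list = field(default_factory=lambda: [ClassSpec("C0"), ClassSpec("C1")])
    base_mean: float = 0.2
    marker_fold: float = 8.0
    dispersion: float = 2.0
    libsize_sigma: float = 0.25
    doublet_rate: float = 0.0
    intermediate_frac_by_age: dict = field(default_factory=dict)
    gradient_class: str | None = None
    gradient_genes: list = field(default_factory=list)
    n_cells: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.array([c.weight for c in self.classes], float)
        if w.sum() <= 0:
            raise ValueError("class weights must sum to a positive value")
        if not 0 <= self.doublet_rate < 0.5:
            raise ValueError("doublet_rate must be in [0, 0.5)")
        demand = sum(c.n_class_markers + c.n_types * c.n_type_markers_per_type
                     for c in self.classes)
        if demand > self.n_genes:
            raise ValueError(
                f"marker demand ({demand} genes) exceeds n_genes ({self.n_genes})"
            )


@dataclass
class _Blueprint:
    """Marker-gene layout and per-type mean profiles (unit depth)."""

    type_names: list
    type_class: dict
    profiles: np.ndarray          # n_types x n_genes mean profile
    precursor: np.ndarray         # n_types x n_genes precursor profile
    class_markers: dict           # class -> gene index array
    type_markers: dict            # type -> gene index array


def _build_blueprint(spec: AtlasSimSpec) -> _Blueprint:
    gene_cursor = 0
    type_names, type_class = [], {}
    class_markers, type_markers = {}, {}
    rows_mature, rows_prec = [], []
    for cls in spec.classes:
        cm = np.arange(gene_cursor, gene_cursor + cls.n_class_markers)
        gene_cursor += cls.n_class_markers
        class_markers[cls.name] = cm
        for t in range(cls.n_types):
            tname = f"{cls.name}.t{t}"
            tm = np.arange(gene_cursor, gene_cursor + cls.n_type_markers_per_type)
            gene_cursor += cls.n_type_markers_per_type
            type_names.append(tname)
            type_class[tname] = cls.name
            type_markers[tname] = tm
            prof = np.full(spec.n_genes, spec.base_mean)
            prof[cm] *= spec.marker_fold
            prec = prof.copy()          # precursor: class identity only
            prof = prof.copy()
            prof[tm] *= spec.marker_fold
            rows_mature.append(prof)
            rows_prec.append(prec)
    return _Blueprint(
        type_names=type_names,
        type_class=type_class,
        profiles=np.array(rows_mature),
        precursor=np.array(rows_prec),
        class_markers=class_markers,
        type_markers=type_markers,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson sample with shared size parameter; Poisson limit at inf."""
    if not np.isfinite(dispersion):
        return rng.poisson(mean)
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 1e-300) / dispersion)
    return rng.poisson(lam)


def _axis_coord(axis: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Map a retinal axis to a [0, 1] coordinate on the unit disk."""
    if axis in ("x", "nasotemporal"):
        return (x + 1.0) / 2.0
    if axis in ("y", "dorsoventral"):
        return (y + 1.0) / 2.0
    if axis in ("r", "radius", "centro-peripheral"):
        return np.sqrt(x**2 + y**2)
    raise ValueError(f"unknown gradient axis {axis!r}")


def simulate_atlas(
    spec: AtlasSimSpec, _blueprint: _Blueprint | None = None
) -> tuple[CountMatrix, GroundTruth]:
    """Draw one atlas: counts plus full per-cell ground truth.

    Counts are gamma-Poisson with cell mean ``libsize * base_mean *
    fold(gene, type)``.  Intermediates mix the precursor and mature mean
    profiles with weight w ~ U(0.3, 0.9) on the precursor.  Doublets are
    the raw sum of two independently drawn singlet count vectors, so they
    carry the characteristic near-2x UMI load the doublet rule targets.
    Identical spec (including seed) yields identical output.
    """
    rng = np.random.default_rng(spec.seed)
    bp = _blueprint if _blueprint is not None else _build_blueprint(spec)
    n_types = len(bp.type_names)
    weights = np.array([c.weight for c in spec.classes], float)
    weights = weights / weights.sum()
    # type probability: class weight split evenly over its types
    type_p = np.concatenate([
        np.full(c.n_types, w / c.n_types)
        for c, w in zip(spec.classes, weights)
    ])

    ages = sorted(spec.intermediate_frac_by_age) or ["adult"]
    age_of_cell = np.array(ages)[rng.integers(0, len(ages), spec.n_cells)]

    type_idx = rng.choice(n_types, size=spec.n_cells, p=type_p)
    libsize = rng.lognormal(mean=0.0, sigma=spec.libsize_sigma, size=spec.n_cells)
    is_doublet = rng.random(spec.n_cells) < spec.doublet_rate
    partner_idx = rng.choice(n_types, size=spec.n_cells, p=type_p)
    partner_lib = rng.lognormal(mean=0.0, sigma=spec.libsize_sigma, size=spec.n_cells)

    inter_frac = np.array([spec.intermediate_frac_by_age.get(a, 0.0) for a in age_of_cell])
    is_inter = (rng.random(spec.n_cells) < inter_frac) & ~is_doublet
    mix_w = np.where(is_inter, rng.uniform(0.3, 0.9, spec.n_cells), 0.0)

    # positions for the gradient class (unit disk, uniform)
    theta = rng.uniform(0, 2 * np.pi, spec.n_cells)
    rad = np.sqrt(rng.uniform(0, 1, spec.n_cells))
    pos_x, pos_y = rad * np.cos(theta), rad * np.sin(theta)

    mean = bp.profiles[type_idx] * libsize[:, None]          # cells x genes
    if is_inter.any():
        mixed = (mix_w[:, None] * bp.precursor[type_idx]
                 + (1 - mix_w[:, None]) * bp.profiles[type_idx]) * libsize[:, None]
        mean[is_inter] = mixed[is_inter]

    in_grad_class = np.zeros(spec.n_cells, bool)
    if spec.gradient_class is not None and spec.gradient_genes:
        cell_class = np.array([bp.type_class[bp.type_names[i]] for i in type_idx])
        in_grad_class = cell_class == spec.gradient_class
        for gene_i, axis in spec.gradient_genes:
            coord = _axis_coord(axis, pos_x, pos_y)
            factor = 1.0 + (spec.marker_fold - 1.0) * coord
            mean[in_grad_class, gene_i] = (
                spec.base_mean * libsize[in_grad_class] * factor[in_grad_class]
            )

    counts = _nb_draw(rng, mean, spec.dispersion)

    if is_doublet.any():
        partner_mean = bp.profiles[partner_idx] * partner_lib[:, None]
        partner_counts = _nb_draw(rng, partner_mean[is_doublet], spec.dispersion)
        counts[is_doublet] += partner_counts

    cells = [f"cell{i:05d}" for i in range(spec.n_cells)]
    cm = CountMatrix(
        counts=sp.csr_matrix(counts.T),      # genes x cells
        genes=[f"g{j:04d}" for j in range(spec.n_genes)],
        cells=cells,
        meta=pd.DataFrame({"age": age_of_cell}, index=pd.Index(cells, name="barcode")),
    )
    truth = GroundTruth(pd.DataFrame({
        "cell": cells,
        "class_label": [bp.type_class[bp.type_names[i]] for i in type_idx],
        "type_label": [bp.type_names[i] for i in type_idx],
        "doublet": is_doublet,
        "type_label_2": np.where(is_doublet, np.array(bp.type_names)[partner_idx], ""),
        "maturity": np.where(is_inter, "intermediate", "mature"),
        "mix_weight": mix_w,
        "pos_x": np.where(in_grad_class, pos_x, np.nan),
        "pos_y": np.where(in_grad_class, pos_y, np.nan),
        "age": age_of_cell,
    }))
    return cm, truth


def marker_table_from_spec(spec: AtlasSimSpec) -> dict[str, set[str]]:
    """Class -> class-marker-gene-name map for a simulated atlas."""
    bp = _build_blueprint(spec)
    return {cls: {f"g{j:04d}" for j in idx} for cls, idx in bp.class_markers.items()}


def simulate_paired_datasets(
    spec: AtlasSimSpec,
    n_datasets: int = 2,
    shared_type_frac: float = 1.0,
    label_noise: float = 0.0,
    shared_gene_frac: float = 1.0,
    mean_perturb_sigma: float = 0.1,
) -> tuple[list[tuple[CountMatrix, GroundTruth]], dict[str, dict[str, str]]]:
    """Draw several datasets ("species"/"ages") sharing a fraction of types.

    Shared types keep their marker-gene layout across datasets; unshared
    types are re-marked on spare genes per dataset.  Each dataset gets a
    gene-wise lognormal mean perturbation (batch shift) and emits genes
    under dataset-specific identifiers.  A homolog table links dataset
    genes to homolog groups; each dataset's table covers a random
    ``shared_gene_frac`` of groups, so the all-datasets intersection is
    what harmonization must recover.  ``label_noise`` relabels that
    fraction of singlet cells with a random wrong type in the ground truth.

    Returns (list of (CountMatrix, GroundTruth), homolog table).
    """
    if n_datasets < 2:
        raise ValueError("n_datasets must be >= 2")
    rng = np.random.default_rng(spec.seed)
    bp = _build_blueprint(spec)
    n_types = len(bp.type_names)
    n_shared = int(round(shared_type_frac * n_types))
    shared_types = set(rng.choice(n_types, size=n_shared, replace=False).tolist())

    out, homologs = [], {}
    for d in range(n_datasets):
        ds_spec = AtlasSimSpec(**{**spec.__dict__, "seed": int(rng.integers(2**31 - 1))})
        bp_d = _build_blueprint(ds_spec)
        # re-mark unshared types on spare genes (or scrambled positions)
        spare = np.setdiff1d(
            np.arange(spec.n_genes),
            np.concatenate([v for v in bp.type_markers.values()]
                           + [v for v in bp.class_markers.values()]),
        )
        cursor = 0
        for ti, tname in enumerate(bp.type_names):
            if ti in shared_types:
                continue
            k = len(bp.type_markers[tname])
            prof = bp_d.profiles[ti]
            prof[bp.type_markers[tname]] = ds_spec.base_mean
            if cursor + k <= len(spare):
                new_idx = spare[cursor:cursor + k]
                cursor += k
                prof[new_idx] = ds_spec.base_mean * spec.marker_fold
        perturb = rng.lognormal(0.0, mean_perturb_sigma, spec.n_genes)
        bp_d.profiles = bp_d.profiles * perturb
        bp_d.precursor = bp_d.precursor * perturb

        cm, truth = simulate_atlas(ds_spec, _blueprint=bp_d)
        ds_name = f"ds{d}"
        cm = CountMatrix(
            counts=cm.counts,
            genes=[f"{ds_name}_{g}" for g in cm.genes],
            cells=[f"{ds_name}_{c}" for c in cm.cells],
            meta=cm.meta.assign(dataset=ds_name).set_axis(
                [f"{ds_name}_{c}" for c in cm.cells], axis=0),
        )
        truth.table["cell"] = [f"{ds_name}_{c}" for c in truth.table["cell"]]
        truth.table["dataset"] = ds_name
        if label_noise > 0:
            singlet = ~truth.table["doublet"].to_numpy()
            flip = (rng.random(len(truth.table)) < label_noise) & singlet
            wrong = rng.integers(0, n_types, flip.sum())
            truth.table.loc[flip, "type_label"] = [bp.type_names[w] for w in wrong]
        out.append((cm, truth))

        covered = rng.random(spec.n_genes) < shared_gene_frac
        homologs[ds_name] = {
            f"{ds_name}_g{j:04d}": f"hg{j:04d}"
            for j in range(spec.n_genes) if covered[j]
        }
    return out, homologs
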