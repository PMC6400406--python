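"""Seeded synthetic data with recorded ground truth.

Two families of generators are provided:

* **Count matrices** (:func:`generate_counts`, :func:`generate_trajectory_counts`)
  emulate droplet scRNA-seq UMI data from a developing kidney: negative-binomial
  counts with cluster-specific means, a handful of exclusive marker genes per
  cell type, designated "stressed" and red-blood-cell subpopulations whose
  mitochondrial / stress-gene / hemoglobin expression fractions exceed the QC
  thresholds, optional batch effects, and an optional latent 1-D developmental
  trajectory with branch topology.

* **Fluorescence images** (:func:`generate_spot_image`,
  :func:`generate_gradient_image`) emulate max-projected smFISH and
  immunostaining micrographs: diffraction-limited Gaussian spots, additive
  autofluorescence, an exponential intensity gradient anchored to a tubule
  contour, and Gaussian camera noise.

Every generator is deterministic given its seed, and returns a
:class:`GroundTruth` recording everything a downstream estimator could be
scored against.

Negative-binomial convention: ``variance = mu + dispersion * mu**2``
(Bioconductor-style; ``dispersion -> 0`` is the Poisson limit).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import CountMatrix, GeneListRegistry, HEMOGLOBIN_GENES, MITOCHONDRIAL_GENES

N_STRESS_GENES = 20
N_RIBO_GENES = 20
N_PROLIF_GENES = 10


class SpecError(ValueError):
    """Raised when a simulation spec is internally inconsistent."""


@dataclass
class TrajectorySpec:
    """Latent 1-D trajectory layout.

    ``branch_topology`` is a list of (parent, child) segment edges; segment 0
    is the root.  The default is a linear chain.  Cells in segment *s* have
    latent time ``depth(s) + u`` with ``u ~ U[0, 1)``.
    """

    n_segments: int = 3
    cells_per_segment: int = 200
    branch_topology: list[tuple[int, int]] | None = None
    n_dynamic_genes: int = 100
    n_monotone_genes: int = 10
    monotone_log_fold: float = 2.0  # total log-fold over the full time span

    def edges(self) -> list[tuple[int, int]]:
        if self.branch_topology is None:
            return [(i, i + 1) for i in range(self.n_segments - 1)]
        return [tuple(e) for e in self.branch_topology]


@dataclass
class CountSimSpec:
    """Parameters of the synthetic UMI count generator.

    Defaults mirror the structure of a single dissected fetal-kidney sample:
    22 final cell types, ~2.5 mean UMI per gene (≈5,000 UMI per cell over
    2,000 genes, matching the reported median of ~4,800 transcripts per
    cell), 4 exclusive 8-fold markers per cluster, and moderate NB
    overdispersion (phi = 0.1).  Stressed / red-blood-cell / low-count
    subpopulations default to zero cells; QC-focused analyses enable them
    with fractions exceeding the filter thresholds at a 2x margin.
    """

    n_clusters: int = 22
    cells_per_cluster: int = 150
    n_genes: int = 2000
    markers_per_cluster: int = 4
    marker_fold: float = 8.0
    baseline_mean: float = 2.5
    dispersion: float = 0.1
    # curated-list genes (mito/stress/hemoglobin) are highly expressed in the
    # cells where they matter; real dispersion decreases with mean, so they
    # get a lower NB dispersion than the gene-level baseline
    special_dispersion: float = 0.02
    depth_sigma: float = 0.25  # lognormal spread of per-cell depth
    gene_abundance_sigma: float = 0.6  # lognormal spread of gene abundances

    # baseline planted fractions for ordinary cells
    mito_fraction: float = 0.02
    stress_fraction: float = 0.01
    hemoglobin_fraction: float = 0.001

    # designated QC-failing subpopulations (appended after the cluster cells)
    n_stressed: int = 0
    stressed_mito_fraction: float = 0.20
    stressed_stress_fraction: float = 0.10
    n_rbc: int = 0
    rbc_hemoglobin_fraction: float = 0.02
    n_low_count: int = 0
    low_count_expected_total: float = 1000.0

    # batch structure: log-normal per-gene offsets for batches > 0
    n_batches: int = 1
    batch_offset_scale: float = 0.0

    # low-rank cluster programs: cluster log-mean offsets spanned by a few
    # latent factors, so cell types occupy a low-dimensional manifold (as in
    # real tissue); marker and curated-list genes carry no program loading
    n_program_factors: int = 8
    program_sigma: float = 0.5  # per-gene sd of the cluster log-offset

    # genes with inflated dispersion (for variability-ranking studies)
    n_overdispersed: int = 0
    overdispersion_factor: float = 10.0

    trajectory: TrajectorySpec | None = None
    seed: int = 0

    # cluster assigned to proliferation-marker elevation (None = no planting)
    proliferative_cluster: int | None = None
    proliferation_fold: float = 4.0

    def validate(self) -> None:
        if self.n_clusters < 1 or self.cells_per_cluster < 1 or self.n_genes < 1:
            raise SpecError("counts parameters must be positive")
        if self.marker_fold <= 1:
            raise SpecError("marker_fold must exceed 1")
        if self.baseline_mean <= 0 or self.dispersion < 0:
            raise SpecError("baseline_mean must be > 0 and dispersion >= 0")
        for f in (self.mito_fraction, self.stress_fraction, self.hemoglobin_fraction,
                  self.stressed_mito_fraction, self.stressed_stress_fraction,
                  self.rbc_hemoglobin_fraction):
            if not 0 <= f < 1:
                raise SpecError("planted fractions must lie in [0, 1)")
        n_special = 13 + 3 + N_STRESS_GENES + N_RIBO_GENES + N_PROLIF_GENES
        if self.markers_per_cluster * self.n_clusters > self.n_genes - n_special:
            raise SpecError(
                f"{self.markers_per_cluster} markers x {self.n_clusters} clusters "
                f"exceed the {self.n_genes - n_special} assignable genes"
            )


@dataclass
class ImageSimSpec:
    """Parameters of the synthetic fluorescence image generators."""

    image_size: tuple[int, int] = (256, 256)
    n_spots: int = 50
    spot_amplitude: float = 100.0
    spot_sigma: float = 1.2  # px, diffraction-limited PSF width
    background_level: float = 10.0
    autofluorescence: np.ndarray | None = None
    autofluorescence_scale: float = 1.0
    decay_length: float = 20.0  # px, gradient lambda
    gradient_amplitude: float = 100.0
    contour: np.ndarray | None = None  # (n, 2) polyline, (row, col) pixels
    noise_sd: float = 1.0
    margin: float = 5.0  # keep spots this far from the border
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise SpecError("image too small")
        if self.n_spots < 0 or self.spot_sigma <= 0 or self.noise_sd < 0:
            raise SpecError("invalid spot/noise parameters")
        if self.autofluorescence is not None and np.asarray(self.autofluorescence).shape != (h, w):
            raise SpecError("autofluorescence template must match image_size")


@dataclass
class GroundTruth:
    """Everything the generators know about what they produced."""

    cluster: np.ndarray | None = None          # per-cell integer labels
    batch: np.ndarray | None = None            # per-cell batch ids
    latent_time: np.ndarray | None = None      # per-cell latent time
    segment: np.ndarray | None = None          # per-cell trajectory segment
    topology: list[tuple[int, int]] | None = None
    marker_genes: dict[int, list[str]] | None = None  # cluster -> planted markers
    marker_fold: float | None = None
    monotone_genes: list[str] | None = None
    overdispersed_genes: list[str] | None = None
    stressed_cells: list[str] | None = None
    rbc_cells: list[str] | None = None
    low_count_cells: list[str] | None = None
    cluster_means: np.ndarray | None = None    # (n_clusters, n_genes) expected means
    spot_centers: np.ndarray | None = None     # (n_spots, 2) (row, col)
    intensity_params: dict | None = None       # generating-function parameters
    contour: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {str(k): conv(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [conv(x) for x in v]
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            return v

        payload = {k: conv(v) for k, v in dataclasses.asdict(self).items() if v is not None}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        kwargs = {}
        array_fields = {"cluster", "batch", "latent_time", "segment", "cluster_means",
                        "spot_centers", "contour"}
        for k, v in payload.items():
            if k in array_fields:
                kwargs[k] = np.asarray(v)
            elif k == "marker_genes":
                kwargs[k] = {int(c): list(g) for c, g in v.items()}
            elif k == "topology":
                kwargs[k] = [tuple(e) for e in v]
            else:
                kwargs[k] = v
        return cls(**kwargs)


def default_registry(include_markers: dict[int, list[str]] | None = None) -> GeneListRegistry:
    """Registry of the curated gene lists used by the synthetic genomes."""
    lists = {
        "mitochondrial": list(MITOCHONDRIAL_GENES),
        "hemoglobin": list(HEMOGLOBIN_GENES),
        "stress_markers": [f"STRESS{i + 1}" for i in range(N_STRESS_GENES)],
        "ribosomal": [f"RPL{i + 1}" for i in range(N_RIBO_GENES)],
        "proliferation_markers": [f"PROLIF{i + 1}" for i in range(N_PROLIF_GENES)],
    }
    if include_markers:
        lists["literature_markers"] = [g for gs in include_markers.values() for g in gs]
    return GeneListRegistry(lists)


def _gene_names(n_genes: int) -> tuple[list[str], dict[str, np.ndarray]]:
    """Gene symbols: curated special lists first, then generic G#### symbols."""
    names: list[str] = []
    names += list(MITOCHONDRIAL_GENES)
    names += list(HEMOGLOBIN_GENES)
    names += [f"STRESS{i + 1}" for i in range(N_STRESS_GENES)]
    names += [f"RPL{i + 1}" for i in range(N_RIBO_GENES)]
    names += [f"PROLIF{i + 1}" for i in range(N_PROLIF_GENES)]
    n_special = len(names)
    if n_genes < n_special + 1:
        raise SpecError(f"need at least {n_special + 1} genes")
    names += [f"G{i + 1:05d}" for i in range(n_genes - n_special)]
    idx = {
        "mito": np.arange(0, 13),
        "hb": np.arange(13, 16),
        "stress": np.arange(16, 16 + N_STRESS_GENES),
        "ribo": np.arange(16 + N_STRESS_GENES, 16 + N_STRESS_GENES + N_RIBO_GENES),
        "prolif": np.arange(16 + N_STRESS_GENES + N_RIBO_GENES, n_special),
        "regular": np.arange(n_special, n_genes),
    }
    return names, idx


def _sample_nb(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray | float):
    """NB draws with variance mu + phi mu^2; Poisson when phi ~ 0."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.zeros(mean.shape, dtype=np.int64)
    pois = phi < 1e-12
    if np.any(pois):
        out[pois] = rng.poisson(mean[pois])
    nb = ~pois & (mean > 0)
    if np.any(nb):
        size = 1.0 / phi[nb]
        p = size / (size + mean[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def generate_counts(spec: CountSimSpec) -> tuple[CountMatrix, GroundTruth]:
    """Generate a clustered NB count matrix with planted markers and QC classes.

    Cells are laid out cluster by cluster, followed by the designated
    stressed, red-blood-cell, and low-count cells (assigned round-robin to
    clusters for their non-special expression).  Planted markers multiply
    their gene's expected mean by ``marker_fold`` in exactly one cluster, so
    the expected COI/rest mean ratio equals ``marker_fold``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names, idx = _gene_names(spec.n_genes)
    n_genes = spec.n_genes

    # relative abundances of non-special genes (lognormal heterogeneity)
    abund = np.ones(n_genes)
    reg = idx["regular"]
    abund[reg] = np.exp(rng.normal(0.0, spec.gene_abundance_sigma, reg.size))
    # special genes participate at baseline abundance 1; their expression is
    # later overwritten by the planted-fraction allocation
    special = np.concatenate([idx["mito"], idx["hb"], idx["stress"]])
    nonspecial_mask = np.ones(n_genes, dtype=bool)
    nonspecial_mask[special] = False

    # assign markers among regular genes only
    marker_pool = rng.permutation(reg)
    marker_genes: dict[int, list[str]] = {}
    fold_matrix = np.ones((spec.n_clusters, n_genes))
    pos = 0
    for k in range(spec.n_clusters):
        gi = marker_pool[pos:pos + spec.markers_per_cluster]
        pos += spec.markers_per_cluster
        marker_genes[k] = [names[g] for g in gi]
        fold_matrix[k, gi] = spec.marker_fold
    if spec.proliferative_cluster is not None:
        fold_matrix[spec.proliferative_cluster, idx["prolif"]] *= spec.proliferation_fold

    # low-rank cluster programs on unassigned regular genes only
    program = np.zeros((spec.n_clusters, n_genes))
    if spec.n_program_factors > 0 and spec.program_sigma > 0:
        free = np.setdiff1d(reg, marker_pool[:pos])
        r = spec.n_program_factors
        loadings = rng.normal(0.0, 1.0, (free.size, r))
        z = rng.normal(0.0, 1.0, (spec.n_clusters, r))
        program[:, free] = spec.program_sigma * (z @ loadings.T) / np.sqrt(r)

    # cluster-level expected relative expression of non-special genes;
    # normalised by the common baseline so planted folds are exact
    z0 = abund[nonspecial_mask].sum()
    rel = (abund[None, :] * fold_matrix * np.exp(program)) / z0  # (n_clusters, n_genes)

    # cell bookkeeping
    n_core = spec.n_clusters * spec.cells_per_cluster
    core_cluster = np.repeat(np.arange(spec.n_clusters), spec.cells_per_cluster)
    n_extra = spec.n_stressed + spec.n_rbc + spec.n_low_count
    extra_cluster = np.arange(n_extra) % spec.n_clusters
    cluster = np.concatenate([core_cluster, extra_cluster]).astype(int)
    n_cells = n_core + n_extra
    cells = [f"CELL{i + 1:05d}" for i in range(n_cells)]

    status = np.array(["ok"] * n_cells, dtype=object)
    s0 = n_core
    status[s0:s0 + spec.n_stressed] = "stressed"
    status[s0 + spec.n_stressed:s0 + spec.n_stressed + spec.n_rbc] = "rbc"
    status[s0 + spec.n_stressed + spec.n_rbc:] = "low_count"

    batch = (np.arange(n_cells) % spec.n_batches).astype(int)
    # per-gene multiplicative batch offsets (batch 0 is the reference)
    batch_log_offsets = np.zeros((spec.n_batches, n_genes))
    for b in range(1, spec.n_batches):
        batch_log_offsets[b, reg] = rng.normal(0.0, spec.batch_offset_scale, reg.size)

    depth = np.exp(rng.normal(0.0, spec.depth_sigma, n_cells))
    base_total = spec.baseline_mean * n_genes
    totals = base_total * depth
    totals[status == "low_count"] = spec.low_count_expected_total * depth[status == "low_count"]

    f_m = np.full(n_cells, spec.mito_fraction)
    f_s = np.full(n_cells, spec.stress_fraction)
    f_h = np.full(n_cells, spec.hemoglobin_fraction)
    f_m[status == "stressed"] = spec.stressed_mito_fraction
    f_s[status == "stressed"] = spec.stressed_stress_fraction
    f_h[status == "rbc"] = spec.rbc_hemoglobin_fraction

    mean = np.zeros((n_genes, n_cells))
    rel_cells = rel[cluster, :] * np.exp(batch_log_offsets[batch, :])  # (n_cells, n_genes)
    rel_cells[:, special] = 0.0
    rel_cells /= rel_cells.sum(axis=1, keepdims=True)
    f_total = f_m + f_s + f_h
    mean[:, :] = (rel_cells * (totals * (1 - f_total))[:, None]).T
    mean[idx["mito"], :] = (totals * f_m)[None, :] / idx["mito"].size
    mean[idx["stress"], :] = (totals * f_s)[None, :] / idx["stress"].size
    mean[idx["hb"], :] = (totals * f_h)[None, :] / idx["hb"].size

    dispersion = np.full(n_genes, spec.dispersion)
    dispersion[special] = spec.special_dispersion
    over: list[str] = []
    if spec.n_overdispersed:
        oi = marker_pool[pos:pos + spec.n_overdispersed]
        dispersion[oi] = spec.dispersion * spec.overdispersion_factor
        over = [names[g] for g in oi]

    counts = _sample_nb(rng, mean, dispersion[:, None])
    cm = CountMatrix(names, cells, counts, batch=batch if spec.n_batches > 1 else None)
    gt = GroundTruth(
        cluster=cluster,
        batch=batch,
        marker_genes=marker_genes,
        marker_fold=spec.marker_fold,
        overdispersed_genes=over or None,
        stressed_cells=[cells[i] for i in np.flatnonzero(status == "stressed")] or None,
        rbc_cells=[cells[i] for i in np.flatnonzero(status == "rbc")] or None,
        low_count_cells=[cells[i] for i in np.flatnonzero(status == "low_count")] or None,
        cluster_means=rel * base_total,
    )
    return cm, gt


def _segment_depths(edges: list[tuple[int, int]], n_segments: int) -> np.ndarray:
    """Depth (root distance in segments) per segment; validates tree shape."""
    children: dict[int, list[int]] = {}
    parents: dict[int, int] = {}
    for p, c in edges:
        children.setdefault(p, []).append(c)
        if c in parents:
            raise SpecError(f"segment {c} has two parents — topology must be a tree")
        parents[c] = p
    roots = [s for s in range(n_segments) if s not in parents]
    if len(roots) != 1:
        raise SpecError(f"topology must have exactly one root segment, found {roots}")
    depth = np.full(n_segments, -1.0)
    stack = [(roots[0], 0.0)]
    while stack:
        s, d = stack.pop()
        if depth[s] >= 0:
            raise SpecError("branch topology contains a cycle")
        depth[s] = d
        for c in children.get(s, []):
            stack.append((c, d + 1.0))
    if np.any(depth < 0):
        raise SpecError("branch topology is disconnected")
    return depth


def generate_trajectory_counts(spec: CountSimSpec) -> tuple[CountMatrix, GroundTruth]:
    """Counts along a latent 1-D (optionally branching) trajectory.

    Gene expected means are piecewise-linear in latent time: dynamic genes
    interpolate seeded log-fold endpoint values along each segment
    (continuous at branch points); monotone genes increase log-linearly with
    latent time over the whole span.
    """
    spec.validate()
    traj = spec.trajectory
    if traj is None:
        raise SpecError("trajectory field must be set")
    edges = traj.edges()
    depth = _segment_depths(edges, traj.n_segments)
    rng = np.random.default_rng(spec.seed)
    names, idx = _gene_names(spec.n_genes)
    n_genes = spec.n_genes
    reg = idx["regular"]

    n_cells = traj.n_segments * traj.cells_per_segment
    segment = np.repeat(np.arange(traj.n_segments), traj.cells_per_segment)
    u = rng.uniform(0.0, 1.0, n_cells)
    # sort within segments so cell order is time order inside each segment
    for s in range(traj.n_segments):
        m = segment == s
        u[m] = np.sort(u[m])
    latent = depth[segment] + u
    cells = [f"CELL{i + 1:05d}" for i in range(n_cells)]

    abund = np.ones(n_genes)
    abund[reg] = np.exp(rng.normal(0.0, spec.gene_abundance_sigma, reg.size))

    pool = rng.permutation(reg)
    dyn = pool[:traj.n_dynamic_genes]
    mono = pool[traj.n_dynamic_genes:traj.n_dynamic_genes + traj.n_monotone_genes]
    # segment-specific marker programs: each segment owns markers_per_cluster
    # genes whose log-fold ramps 0 -> log(marker_fold) within the segment and
    # stays on in all descendant segments (fate identity accumulates)
    pos = traj.n_dynamic_genes + traj.n_monotone_genes
    seg_markers: dict[int, np.ndarray] = {}
    for s in range(traj.n_segments):
        seg_markers[s] = pool[pos:pos + spec.markers_per_cluster]
        pos += spec.markers_per_cluster
    if pos > pool.size:
        raise SpecError("not enough genes for dynamic + monotone + segment markers")

    # endpoint log-folds per segment for dynamic genes, continuous across edges
    parents = {c: p for p, c in edges}
    start_lf = np.zeros((traj.n_segments, dyn.size))
    end_lf = rng.normal(0.0, 1.0, (traj.n_segments, dyn.size))
    order = np.argsort(depth)
    for s in order:
        if s in parents:
            start_lf[s] = end_lf[parents[s]]

    t_span = depth.max() + 1.0
    log_mean = np.tile(np.log(abund), (n_cells, 1))  # (n_cells, n_genes)
    lf_cells = start_lf[segment] * (1 - u[:, None]) + end_lf[segment] * u[:, None]
    log_mean[:, dyn] += lf_cells
    log_mean[:, mono] += traj.monotone_log_fold * (latent / t_span)[:, None]
    lmf = np.log(spec.marker_fold)
    parent_of = {c: p for p, c in edges}
    ancestors: dict[int, set[int]] = {}
    for s in range(traj.n_segments):
        anc, cur = set(), s
        while cur in parent_of:
            cur = parent_of[cur]
            anc.add(cur)
        ancestors[s] = anc
    for s, genes_s in seg_markers.items():
        own = segment == s
        log_mean[np.ix_(own, genes_s)] += (u[own] * lmf)[:, None]
        for c in range(traj.n_segments):
            if s in ancestors[c]:
                log_mean[np.ix_(segment == c, genes_s)] += lmf

    rel = np.exp(log_mean)
    rel /= rel.sum(axis=1, keepdims=True)
    depth_c = np.exp(rng.normal(0.0, spec.depth_sigma, n_cells))
    totals = spec.baseline_mean * n_genes * depth_c
    mean = (rel * totals[:, None]).T
    counts = _sample_nb(rng, mean, spec.dispersion)

    gt = GroundTruth(
        latent_time=latent,
        segment=segment,
        topology=edges,
        monotone_genes=[names[g] for g in mono],
        marker_genes={s: [names[g] for g in gs] for s, gs in seg_markers.items()},
        marker_fold=spec.marker_fold,
        cluster=segment.copy(),
    )
    return CountMatrix(names, cells, counts), gt


# ---------------------------------------------------------------------------
# images


def generate_spot_image(spec: ImageSimSpec) -> tuple[np.ndarray, GroundTruth]:
    """Synthetic smFISH field: Gaussian spots over background + autofluorescence.

    ``image = background + alpha * autofluorescence + sum of Gaussians + noise``.
    Spot centers are drawn uniformly inside the margin and recorded.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    img = np.full((h, w), spec.background_level, dtype=float)
    if spec.autofluorescence is not None:
        img += spec.autofluorescence_scale * np.asarray(spec.autofluorescence, dtype=float)

    centers = np.column_stack([
        rng.uniform(spec.margin, h - 1 - spec.margin, spec.n_spots),
        rng.uniform(spec.margin, w - 1 - spec.margin, spec.n_spots),
    ]) if spec.n_spots else np.zeros((0, 2))
    if centers.size and (
        centers.min() < 0 or centers[:, 0].max() > h - 1 or centers[:, 1].max() > w - 1
    ):
        raise SpecError("spot outside image bounds")

    half = int(np.ceil(4 * spec.spot_sigma))
    for r0, c0 in centers:
        r1, r2 = int(np.floor(r0)) - half, int(np.floor(r0)) + half + 1
        c1, c2 = int(np.floor(c0)) - half, int(np.floor(c0)) + half + 1
        r1, c1 = max(r1, 0), max(c1, 0)
        r2, c2 = min(r2, h), min(c2, w)
        rr, cc = np.meshgrid(np.arange(r1, r2), np.arange(c1, c2), indexing="ij")
        img[r1:r2, c1:c2] += spec.spot_amplitude * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * spec.spot_sigma ** 2)
        )
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, (h, w))

    gt = GroundTruth(
        spot_centers=centers,
        intensity_params={
            "background_level": spec.background_level,
            "spot_amplitude": spec.spot_amplitude,
            "spot_sigma": spec.spot_sigma,
            "noise_sd": spec.noise_sd,
        },
    )
    return img, gt


def polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to the nearest polyline segment.

    ``points``: (n, 2); ``polyline``: (m, 2) ordered vertices, m >= 2.
    """
    points = np.asarray(points, dtype=float)
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2:
        raise SpecError("contour must have at least 2 points")
    a = poly[:-1]  # (m-1, 2)
    b = poly[1:]
    ab = b - a
    denom = (ab ** 2).sum(axis=1)
    degenerate = denom < 1e-30
    if np.all(degenerate):
        raise SpecError("degenerate contour (all points coincide)")
    denom = np.where(degenerate, 1.0, denom)
    # (n, m-1) projection parameter, clamped to the segment
    ap = points[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / denom[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def generate_gradient_image(spec: ImageSimSpec) -> tuple[np.ndarray, GroundTruth]:
    """Exponential intensity gradient around a contour polyline.

    ``I(pixel) = amplitude * exp(-d(pixel, contour) / decay_length)
    + background + noise`` where *d* is the distance to the nearest contour
    segment.
    """
    spec.validate()
    if spec.contour is None:
        raise SpecError("contour polyline required for a gradient image")
    contour = np.asarray(spec.contour, dtype=float)
    if contour.shape[0] < 2 or np.allclose(contour, contour[0]):
        raise SpecError("degenerate (single-point) contour")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d = polyline_distance(pts, contour).reshape(h, w)
    img = spec.gradient_amplitude * np.exp(-d / spec.decay_length) + spec.background_level
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, (h, w))
    gt = GroundTruth(
        contour=contour,
        intensity_params={
            "decay_length": spec.decay_length,
            "gradient_amplitude": spec.gradient_amplitude,
            "background_level": spec.background_level,
            "noise_sd": spec.noise_sd,
        },
    )
    return img, gt
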