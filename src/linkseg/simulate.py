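"""Ground-truthed synthetic tissue generator.

Emulates the failure modes that make transcript-to-cell assignment hard in
imaging-based spatial transcriptomics: adjacent cells sharing boundaries
(cell territories are a bounded Voronoi tessellation, so neighbors touch),
mostly-cytoplasmic transcript placement with only a minority of molecules
inside the nucleus, a fraction of transcripts displaced by isotropic
Gaussian diffusion, and a fraction of cells lacking a detectable nucleus.
Every transcript records its true source cell, giving downstream stages an
exact accuracy oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi
from shapely import affinity
from shapely.geometry import Polygon, box

from .io import BoundarySet, ReferenceMatrix


class GenerationError(RuntimeError):
    """The requested tissue cannot be laid out (extent too small for n_cells)."""


@dataclass(frozen=True)
class TissueParams:
    """Knobs of the synthetic tissue; defaults define the standard regime.

    extent
        Width and height of the tissue patch in micrometers.
    n_cells, n_genes, n_types, markers_per_type
        Tissue composition; marker genes are designated per type and are
        exclusive to it by construction.
    transcripts_per_cell_mean
        Poisson mean of detected molecules per cell.
    nuclear_fraction
        Share of a cell's transcripts placed inside its nucleus; the default
        0.2 leaves roughly 4x more cytoplasmic than nuclear molecules,
        mirroring the dominance of cytoplasmic transcripts in real tissue.
    diffusion_fraction, diffusion_sigma
        Share of transcripts displaced by an isotropic Gaussian of this
        scale (micrometers), emulating molecular diffusion between cells.
    nucleus_free_fraction
        Share of cells with no detectable nucleus (floor of fraction x n).
    nucleus_scale
        Linear scale of the nucleus polygon relative to its cell territory.
    min_spacing
        Minimum distance between cell seed points in micrometers (cells
        cannot be arbitrarily small); the extent must be able to host
        n_cells at this spacing.
    """

    extent: tuple[float, float] = (200.0, 200.0)
    n_cells: int = 200
    n_genes: int = 60
    n_types: int = 5
    markers_per_type: int = 4
    transcripts_per_cell_mean: float = 60.0
    nuclear_fraction: float = 0.2
    diffusion_fraction: float = 0.05
    diffusion_sigma: float = 2.0
    nucleus_free_fraction: float = 0.1
    nucleus_scale: float = 0.5
    min_spacing: float = 4.0
    marker_boost: float = 10.0
    quality: float = 40.0
    z_thickness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nuclear_fraction", "diffusion_fraction", "nucleus_free_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_types > self.n_cells:
            raise ValueError("n_types cannot exceed n_cells")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError("markers_per_type x n_types cannot exceed n_genes")
        if not 0.0 < self.nucleus_scale <= 1.0:
            raise ValueError("nucleus_scale must be in (0, 1]")


@dataclass
class GroundTruth:
    """True generative state of a simulated tissue patch."""

    true_assignment: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    true_type: dict[str, str] = field(default_factory=dict)
    true_cell_polygon: dict[str, Polygon] = field(default_factory=dict)
    true_nucleus_polygon: dict[str, Polygon] = field(default_factory=dict)


@dataclass
class SimulatedTissue:
    transcripts: pd.DataFrame
    cells: BoundarySet
    nuclei: BoundarySet
    reference: ReferenceMatrix
    truth: GroundTruth
    params: TissueParams


def derive_reference(
    n_genes: int,
    n_types: int,
    markers_per_type: int,
    marker_boost: float = 10.0,
    seed: int = 0,
) -> ReferenceMatrix:
    """Build a gene x cell-type reference with designated exclusive markers.

    Background expression is a uniform positive baseline per gene and type.
    The first ``markers_per_type`` x ``n_types`` genes are designated markers
    in consecutive blocks; a marker is boosted by ``marker_boost`` in its own
    type and silenced in every other type, so marker pairs from different
    types are mutually exclusive at the detection level. Columns are
    normalized to sum to one.
    """
    if markers_per_type * n_types > n_genes:
        raise ValueError("markers_per_type x n_types cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    cell_types = [f"T{j}" for j in range(n_types)]
    expr = rng.uniform(0.5, 1.5, size=(n_genes, n_types))
    markers: dict[str, set[str]] = {}
    for j in range(n_types):
        idx = np.arange(j * markers_per_type, (j + 1) * markers_per_type)
        markers[cell_types[j]] = {genes[i] for i in idx}
        others = [k for k in range(n_types) if k != j]
        expr[np.ix_(idx, others)] = 0.0
        expr[idx, j] *= marker_boost
    expr /= expr.sum(axis=0, keepdims=True)
    return ReferenceMatrix(genes=genes, cell_types=cell_types, mean_expr=expr, markers=markers)


def _place_seeds(params: TissueParams, rng: np.random.Generator) -> np.ndarray:
    """Uniform seed points with a soft minimum spacing (dart throwing)."""
    w, h = params.extent
    min_spacing = max(params.min_spacing, 0.3 * np.sqrt(w * h / params.n_cells))
    # a disc-packing bound with slack: beyond ~half of the packing limit,
    # dart throwing stalls and the layout is biologically implausible anyway
    if 2.0 * params.n_cells * min_spacing**2 > w * h:
        raise GenerationError("extent too small to host n_cells at minimum spacing")
    seeds: list[np.ndarray] = []
    attempts = 0
    while len(seeds) < params.n_cells:
        attempts += 1
        if attempts > 200 * params.n_cells:
            raise GenerationError("extent too small to host n_cells at minimum spacing")
        p = rng.uniform((0, 0), (w, h))
        if not seeds or np.min(np.hypot(*(p - np.asarray(seeds)).T)) >= min_spacing:
            seeds.append(p)
    return np.asarray(seeds)


def _bounded_voronoi(seeds: np.ndarray, extent: tuple[float, float]) -> list[Polygon]:
    """Voronoi regions clipped to the extent rectangle.

    Mirroring every seed across the four extent edges makes all interior
    regions finite, after which clipping to the box is exact.
    """
    w, h = extent
    mirrored = [seeds]
    for axis, bound in ((0, 0.0), (0, w), (1, 0.0), (1, h)):
        m = seeds.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    frame = box(0.0, 0.0, w, h)
    polys = []
    for i in range(len(seeds)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region:
            raise GenerationError("unbounded Voronoi region after mirroring")
        verts = vor.vertices[region]
        poly = Polygon(verts).intersection(frame)
        if poly.is_empty or poly.area <= 0:
            raise GenerationError("degenerate Voronoi region; extent too small")
        polys.append(shapely.make_valid(poly))
    return polys


def simulate_cell_map(params: TissueParams) -> tuple[BoundarySet, BoundarySet, GroundTruth]:
    """Lay out cell territories, nuclei and cell types.

    Cell territories are bounded Voronoi regions of uniformly placed seeds,
    clipped to the extent; nuclei are the territories shrunk linearly toward
    their centroid by ``nucleus_scale``. A floor(nucleus_free_fraction x
    n_cells)-sized random subset of cells receives no nucleus. Fully
    deterministic under the seed.
    """
    rng = np.random.default_rng(params.seed)
    seeds = _place_seeds(params, rng)
    polys = _bounded_voronoi(seeds, params.extent)
    cell_ids = [f"c{i:04d}" for i in range(params.n_cells)]
    cells = {cid: poly for cid, poly in zip(cell_ids, polys)}

    n_free = int(np.floor(params.nucleus_free_fraction * params.n_cells))
    free = set(rng.choice(params.n_cells, size=n_free, replace=False).tolist())
    nuclei = {}
    for i, cid in enumerate(cell_ids):
        if i in free:
            continue
        c = cells[cid].centroid
        nuclei[cid] = affinity.scale(
            cells[cid], xfact=params.nucleus_scale, yfact=params.nucleus_scale, origin=c
        )

    types = [f"T{j}" for j in rng.integers(0, params.n_types, size=params.n_cells)]
    truth = GroundTruth(
        true_type=dict(zip(cell_ids, types)),
        true_cell_polygon=dict(cells),
        true_nucleus_polygon=dict(nuclei),
    )
    return (
        BoundarySet(polygons=cells, kind="cell"),
        BoundarySet(polygons=nuclei, kind="nucleus"),
        truth,
    )


def _uniform_in_polygon(
    poly: Polygon, n: int, rng: np.random.Generator, exclude: Polygon | None = None
) -> np.ndarray:
    """Rejection-sample n uniform points in poly (minus ``exclude``)."""
    out = np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 10_000:
            raise GenerationError("rejection sampling failed; degenerate polygon")
        m = max(4 * (n - len(out)), 16)
        pts = rng.uniform((minx, miny), (maxx, maxy), size=(m, 2))
        keep = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
        if exclude is not None:
            keep &= ~shapely.contains_xy(exclude, pts[:, 0], pts[:, 1])
        out = np.vstack([out, pts[keep]])
    return out[:n]


def sample_transcripts(
    params: TissueParams, truth: GroundTruth, ref: ReferenceMatrix
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw typed transcripts for a laid-out cell map.

    Per cell the molecule count is Poisson(transcripts_per_cell_mean) and
    gene identities follow the cell type's normalized expression profile.
    Placement is uniform in the nucleus with probability nuclear_fraction
    (uniform in the whole territory for nucleus-free cells) and uniform in
    the cytoplasm otherwise; a diffusion_fraction subset is then displaced
    by a per-axis Gaussian of scale diffusion_sigma. ``true_assignment``
    records the source cell regardless of where a molecule lands.
    """
    rng = np.random.default_rng(params.seed + 1)
    gene_arr = np.asarray(ref.genes)
    rows_xy: list[np.ndarray] = []
    rows_gene: list[np.ndarray] = []
    rows_cell: list[str] = []
    for cid, poly in truth.true_cell_polygon.items():
        count = rng.poisson(params.transcripts_per_cell_mean)
        if count == 0:
            continue
        profile = ref.profile(truth.true_type[cid])
        genes = gene_arr[rng.choice(len(gene_arr), size=count, p=profile)]
        nucleus = truth.true_nucleus_polygon.get(cid)
        in_nucleus = rng.random(count) < params.nuclear_fraction
        pts = np.empty((count, 2))
        n_nuc = int(in_nucleus.sum())
        if n_nuc:
            target = nucleus if nucleus is not None else poly
            pts[in_nucleus] = _uniform_in_polygon(target, n_nuc, rng)
        if count - n_nuc:
            pts[~in_nucleus] = _uniform_in_polygon(poly, count - n_nuc, rng, exclude=nucleus)
        rows_xy.append(pts)
        rows_gene.append(genes)
        rows_cell.extend([cid] * count)
    xy = np.vstack(rows_xy) if rows_xy else np.empty((0, 2))
    genes_all = np.concatenate(rows_gene) if rows_gene else np.empty(0, dtype=object)

    n = len(xy)
    diffused = rng.random(n) < params.diffusion_fraction
    displacement = rng.normal(0.0, params.diffusion_sigma or 0.0, size=(n, 2))
    xy = xy + diffused[:, None] * displacement
    z = rng.uniform(0.0, params.z_thickness, size=n) if params.z_thickness > 0 else np.zeros(n)

    tids = [f"t{i:06d}" for i in range(n)]
    transcripts = pd.DataFrame(
        {
            "transcript_id": tids,
            "gene": genes_all,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "z": z,
            "quality": params.quality,
            "prior_cell_id": pd.NA,
        }
    )
    truth = replace_truth_assignment(truth, pd.Series(rows_cell, index=tids, dtype=object))
    return transcripts.sort_values("transcript_id").reset_index(drop=True), truth


def replace_truth_assignment(truth: GroundTruth, assignment: pd.Series) -> GroundTruth:
    truth.true_assignment = assignment
    return truth


def simulate(params: TissueParams | None = None, **overrides) -> SimulatedTissue:
    """End-to-end tissue simulation: cell map, reference, transcripts.

    ``overrides`` are TissueParams fields, e.g. ``simulate(seed=3,
    diffusion_fraction=0.0)``.
    """
    params = replace(params or TissueParams(), **overrides)
    ref = derive_reference(
        params.n_genes,
        params.n_types,
        params.markers_per_type,
        marker_boost=params.marker_boost,
        seed=params.seed,
    )
    cells, nuclei, truth = simulate_cell_map(params)
    transcripts, truth = sample_transcripts(params, truth, ref)
    return SimulatedTissue(
        transcripts=transcripts, cells=cells, nuclei=nuclei, reference=ref,
        truth=truth, params=params,
    )


def sample_reference_cells(
    ref: ReferenceMatrix,
    cells_per_type: int = 100,
    depth: float = 200.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pseudo single-cell counts drawn from the reference profiles.

    Stands in for the parallel scRNA-seq experiment used to pick mutually
    exclusive gene pairs: per simulated cell of each type, gene counts are
    Poisson with mean ``depth`` x the type's normalized profile.

    Returns (cells x genes count DataFrame, cell -> type Series).
    """
    rng = np.random.default_rng(seed)
    blocks, labels, index = [], [], []
    for ctype in ref.cell_types:
        lam = depth * ref.profile(ctype)
        counts = rng.poisson(lam[None, :].repeat(cells_per_type, axis=0))
        blocks.append(counts)
        labels.extend([ctype] * cells_per_type)
        index.extend([f"ref_{ctype}_{i:04d}" for i in range(cells_per_type)])
    counts = pd.DataFrame(np.vstack(blocks), index=index, columns=ref.genes)
    return counts, pd.Series(labels, index=index)
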