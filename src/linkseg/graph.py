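"""Heterogeneous graph construction from transcripts and boundaries.

Transcripts and cells are distinct node types. Transcript-transcript edges
connect spatial k-nearest neighbors; transcript-cell candidate edges connect
each transcript to nearby nuclei and carry training labels derived from
boundary overlap: the edge to the nucleus containing a transcript is
positive, edges to other nearby nuclei are negative, and transcripts
contained by no nucleus contribute only unlabeled edges. Large extents are
split into rectangular tiles with padded margins wide enough that a core
transcript's entire scoring neighborhood lives inside its own tile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, box
from shapely.strtree import STRtree

from .embeddings import GeneEmbedding
from .io import BoundarySet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GraphConfig:
    """Spatial-graph thresholds, all in micrometers.

    The default padded margin covers the scoring receptive field of a core
    transcript: its candidate cells lie within ``tc_max_dist``, those cells
    attend over their own candidate transcripts (another ``tc_max_dist``),
    transcript states feeding that attention see one further transcript-hop
    (``tt_max_dist``), and each profile-refinement iteration at inference
    adds one more candidate-plus-neighborhood hop. Closing the receptive
    field inside the padded tile is what makes tiled and untiled
    segmentation agree exactly.
    """

    k_tt: int = 5
    tt_max_dist: float = 5.0
    k_cells: int = 4
    tc_max_dist: float = 15.0
    z_scale: float = 1.0
    tile_target: int = 10_000
    margin: float | None = None
    missing_gene: str = "error"  # or "zero"
    refine_iters: int = 1

    @property
    def effective_margin(self) -> float:
        if self.margin is not None:
            return self.margin
        r = max(self.refine_iters, 0)
        return (2.0 + r) * self.tc_max_dist + (1.0 + r) * self.tt_max_dist


# tc edge labels
POSITIVE, NEGATIVE, UNLABELED = 1, 0, -1


@dataclass
class HeteroGraph:
    """One tile's graph: node tables plus typed edge arrays (index-based)."""

    transcript_ids: np.ndarray
    t_pos: np.ndarray  # (Nt, 3)
    t_feat: np.ndarray  # (Nt, d_emb)
    t_gene_idx: np.ndarray  # (Nt,) index into the embedding vocabulary (-1 if absent)
    is_core: np.ndarray  # (Nt,) bool
    cell_ids: np.ndarray
    c_feat: np.ndarray  # (Nc, 6) standardized geometry
    c_centroid: np.ndarray  # (Nc, 2)
    c_radius: np.ndarray  # (Nc,) equivalent-circle radius sqrt(area/pi), um
    tt_src: np.ndarray
    tt_dst: np.ndarray
    tt_dist: np.ndarray
    tc_t: np.ndarray
    tc_c: np.ndarray
    tc_dist: np.ndarray  # centroid distance, um
    tc_pdist: np.ndarray  # distance to the nucleus outline, um (0 inside)
    tc_label: np.ndarray  # int8 in {POSITIVE, NEGATIVE, UNLABELED}

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def validate(self) -> None:
        if len(self.tt_src) and (self.tt_src.max() >= self.n_transcripts):
            raise ValueError("tt edge endpoint out of range")
        if len(self.tc_t) and (self.tc_t.max() >= self.n_transcripts or self.tc_c.max() >= self.n_cells):
            raise ValueError("tc edge endpoint out of range")
        fwd = set(zip(self.tt_src.tolist(), self.tt_dst.tolist()))
        if any((d, s) not in fwd for s, d in fwd):
            raise ValueError("tt edges not symmetric")
        pos_t = self.tc_t[self.tc_label == POSITIVE]
        if len(pos_t) != len(set(pos_t.tolist())):
            raise ValueError("a transcript has more than one positive tc edge")


@dataclass(frozen=True)
class Tile:
    core: tuple[float, float, float, float]  # x0, y0, x1, y1
    padded: tuple[float, float, float, float]


@dataclass
class TilePlan:
    tiles: list[Tile]
    extent: tuple[float, float, float, float]
    margin: float
    tile_target: int

    def core_mask(self, x: np.ndarray, y: np.ndarray, i: int) -> np.ndarray:
        """Half-open core membership; the global max edges are closed so
        every point belongs to exactly one tile."""
        x0, y0, x1, y1 = self.tiles[i].core
        gx1, gy1 = self.extent[2], self.extent[3]
        right = (x <= x1) if x1 == gx1 else (x < x1)
        top = (y <= y1) if y1 == gy1 else (y < y1)
        return (x >= x0) & right & (y >= y0) & top

    def padded_mask(self, x: np.ndarray, y: np.ndarray, i: int) -> np.ndarray:
        x0, y0, x1, y1 = self.tiles[i].padded
        return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)


def label_by_overlap(transcripts: pd.DataFrame, nuclei: BoundarySet) -> pd.Series:
    """Map each transcript to the unique nucleus covering its (x, y).

    Points on a nucleus outline count as inside. Transcripts covered by no
    nucleus, or ambiguously by several overlapping nuclei, map to None (the
    ambiguous ones are counted in the log).
    """
    ids = list(nuclei.polygons)
    result = pd.Series(
        [None] * len(transcripts), index=transcripts["transcript_id"].to_numpy(), dtype=object
    )
    if not ids or transcripts.empty:
        return result
    tree = STRtree(list(nuclei.polygons.values()))
    pts = shapely.points(transcripts["x"].to_numpy(), transcripts["y"].to_numpy())
    ti, ni = tree.query(pts, predicate="covered_by")
    counts = np.bincount(ti, minlength=len(transcripts))
    unique = counts[ti] == 1
    for t_idx, n_idx in zip(ti[unique], ni[unique]):
        result.iloc[t_idx] = ids[n_idx]
    n_ambiguous = int((counts > 1).sum())
    if n_ambiguous:
        logger.info("%d transcripts inside multiple overlapping nuclei left unlabeled", n_ambiguous)
    return result


def knn_tt_edges(
    transcripts: pd.DataFrame,
    k: int = 5,
    max_dist: float = 5.0,
    z_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric k-nearest-neighbor edges between transcripts.

    Distance is sqrt(dx^2 + dy^2 + (z_scale*dz)^2). Pairs farther than
    ``max_dist`` are dropped, self-edges never occur, and exact distance
    ties are broken toward the smaller transcript_id. Returns (src, dst,
    dist) index arrays containing both directions of every edge.
    """
    n = len(transcripts)
    empty = (np.empty(0, dtype=np.int64),) * 2 + (np.empty(0),)
    if n < 2 or k < 1 or max_dist <= 0:
        return empty
    # transcripts are kept sorted by id, so index order == id order
    X = np.column_stack(
        [transcripts["x"].to_numpy(), transcripts["y"].to_numpy(),
         z_scale * transcripts["z"].to_numpy()]
    )
    tree = cKDTree(X)
    kq = min(n, k + 9)  # over-query so distance ties can be re-sorted by id
    dist, idx = tree.query(X, k=kq)
    undirected: set[tuple[int, int]] = set()
    dists: dict[tuple[int, int], float] = {}
    for i in range(n):
        order = np.lexsort((idx[i], np.round(dist[i], 9)))
        taken = 0
        for j in order:
            nb = int(idx[i][j])
            d = float(dist[i][j])
            if nb == i or not np.isfinite(d):
                continue
            if d > max_dist:
                break
            key = (min(i, nb), max(i, nb))
            undirected.add(key)
            dists.setdefault(key, d)
            taken += 1
            if taken == k:
                break
    if not undirected:
        return empty
    pairs = np.array(sorted(undirected), dtype=np.int64)
    d = np.array([dists[tuple(p)] for p in pairs])
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return src, dst, np.concatenate([d, d])


def candidate_tc_edges(
    transcripts: pd.DataFrame,
    nuclei: BoundarySet,
    overlap: pd.Series,
    k_cells: int = 4,
    max_dist: float = 15.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Candidate transcript-cell edges with overlap-derived labels.

    Each transcript links to its ``k_cells`` nearest nuclei by centroid
    distance within ``max_dist``; the edge to its containing nucleus (if
    any) is always included and labeled positive, the other edges negative.
    Transcripts inside no nucleus get only unlabeled edges. Returns
    (t_index, c_index, dist, label).
    """
    cell_ids = list(nuclei.polygons)
    if not cell_ids or transcripts.empty:
        return (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0), np.empty(0),
                np.empty(0, np.int8))
    cent = np.array([[p.centroid.x, p.centroid.y] for p in nuclei.polygons.values()])
    cix = {cid: i for i, cid in enumerate(cell_ids)}
    X = np.column_stack([transcripts["x"].to_numpy(), transcripts["y"].to_numpy()])
    tree = cKDTree(cent)
    kq = min(len(cell_ids), k_cells)
    dist, idx = tree.query(X, k=kq, distance_upper_bound=max_dist)
    dist = np.atleast_2d(dist.T).T if dist.ndim == 1 else dist
    idx = np.atleast_2d(idx.T).T if idx.ndim == 1 else idx
    overlap_arr = overlap.reindex(transcripts["transcript_id"].to_numpy()).to_numpy(dtype=object)

    t_out, c_out, d_out, l_out = [], [], [], []
    n_isolated = 0
    for i in range(len(transcripts)):
        own = overlap_arr[i]
        own_j = cix.get(own) if own is not None else None
        cand: dict[int, float] = {}
        for d, j in zip(dist[i], idx[i]):
            if np.isfinite(d) and j < len(cell_ids):
                cand[int(j)] = float(d)
        if own_j is not None and own_j not in cand:
            cand[own_j] = float(np.hypot(*(X[i] - cent[own_j])))
        if not cand:
            n_isolated += 1
            continue
        for j in sorted(cand):
            t_out.append(i)
            c_out.append(j)
            d_out.append(cand[j])
            if own_j is None:
                l_out.append(UNLABELED)
            else:
                l_out.append(POSITIVE if j == own_j else NEGATIVE)
    if n_isolated:
        logger.warning("%d transcripts have no nucleus within %.1f um", n_isolated, max_dist)
    t_out = np.asarray(t_out, np.int64)
    c_out = np.asarray(c_out, np.int64)
    polys = np.asarray(list(nuclei.polygons.values()), dtype=object)
    pts = shapely.points(X[t_out, 0], X[t_out, 1]) if len(t_out) else np.empty(0, object)
    pd_out = shapely.distance(pts, polys[c_out]) if len(t_out) else np.empty(0)
    return (
        t_out,
        c_out,
        np.asarray(d_out, float),
        np.asarray(pd_out, float),
        np.asarray(l_out, np.int8),
    )


def cell_geom_features(polygon: Polygon, n_inside: int = 0) -> np.ndarray:
    """Geometric descriptors of a boundary polygon.

    Returns [area, perimeter, circularity 4*pi*A/P^2, elongation
    (minor/major second-moment axis ratio), convexity A/A_hull,
    log1p(transcript count inside)].
    """
    if polygon.is_empty or polygon.area <= 0:
        raise ValueError("degenerate polygon")
    area = polygon.area
    perim = polygon.length
    circularity = min(4.0 * np.pi * area / perim**2, 1.0)
    convexity = min(area / polygon.convex_hull.area, 1.0)

    xs, ys = np.asarray(polygon.exterior.coords.xy)
    x0, y0, x1, y1 = xs[:-1], ys[:-1], xs[1:], ys[1:]
    cross = x0 * y1 - x1 * y0
    a = cross.sum() / 2.0
    cx = ((x0 + x1) * cross).sum() / (6.0 * a)
    cy = ((y0 + y1) * cross).sum() / (6.0 * a)
    # area second moments about the centroid (shoelace forms)
    e_xx = ((x0**2 + x0 * x1 + x1**2) * cross).sum() / (12.0 * a) - cx**2
    e_yy = ((y0**2 + y0 * y1 + y1**2) * cross).sum() / (12.0 * a) - cy**2
    e_xy = ((x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0) * cross).sum() / (24.0 * a) - cx * cy
    cov = np.array([[e_xx, e_xy], [e_xy, e_yy]])
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0.0, None)
    elongation = float(np.sqrt(lam[0] / lam[1])) if lam[1] > 0 else 1.0
    return np.array([area, perim, circularity, elongation, convexity, np.log1p(n_inside)])


def geom_feature_table(nuclei: BoundarySet, inside_counts: dict[str, int]) -> np.ndarray:
    return np.array(
        [cell_geom_features(p, inside_counts.get(cid, 0)) for cid, p in nuclei.polygons.items()]
    ) if len(nuclei) else np.empty((0, 6))


def plan_tiles(transcripts: pd.DataFrame, tile_target: int = 10_000, margin: float = 15.0) -> TilePlan:
    """Split the data extent by recursive bisection along the longer axis
    until every core tile holds at most ``tile_target`` transcripts."""
    if tile_target < 1:
        raise ValueError("tile_target must be >= 1")
    if transcripts.empty:
        ext = (0.0, 0.0, 0.0, 0.0)
        return TilePlan([Tile(ext, ext)], ext, margin, tile_target)
    x = transcripts["x"].to_numpy()
    y = transcripts["y"].to_numpy()
    ext = (float(x.min()), float(y.min()), float(x.max()), float(y.max()))

    tiles: list[tuple[float, float, float, float]] = []

    def split(rect, mask):
        if mask.sum() <= tile_target:
            tiles.append(rect)
            return
        x0, y0, x1, y1 = rect
        axis = 0 if (x1 - x0) >= (y1 - y0) else 1
        coord = x if axis == 0 else y
        lo, hi = (x0, x1) if axis == 0 else (y0, y1)
        cut = float(np.median(coord[mask]))
        if not lo < cut < hi:
            cut = (lo + hi) / 2.0
        left = mask & (coord < cut)
        right = mask & (coord >= cut)
        if not left.any() or not right.any():
            tiles.append(rect)  # cannot bisect further (coincident points)
            return
        if axis == 0:
            split((x0, y0, cut, y1), left)
            split((cut, y0, x1, y1), right)
        else:
            split((x0, y0, x1, cut), left)
            split((x0, cut, x1, y1), right)

    split(ext, np.ones(len(transcripts), dtype=bool))

    def pad(rect):
        x0, y0, x1, y1 = rect
        return (
            max(x0 - margin, ext[0]),
            max(y0 - margin, ext[1]),
            min(x1 + margin, ext[2]),
            min(y1 + margin, ext[3]),
        )

    return TilePlan([Tile(core=r, padded=pad(r)) for r in tiles], ext, margin, tile_target)


@dataclass
class FeatureStats:
    mean: np.ndarray
    std: np.ndarray

    def apply(self, feats: np.ndarray) -> np.ndarray:
        return (feats - self.mean) / self.std


def compute_feature_stats(feats: np.ndarray) -> FeatureStats:
    if len(feats) == 0:
        return FeatureStats(mean=np.zeros(6), std=np.ones(6))
    std = feats.std(axis=0)
    return FeatureStats(mean=feats.mean(axis=0), std=np.where(std > 0, std, 1.0))


def build_tile_graph(
    tile: Tile,
    plan: TilePlan,
    tile_index: int,
    transcripts: pd.DataFrame,
    nuclei: BoundarySet,
    embedding: GeneEmbedding,
    cfg: GraphConfig,
    feat_stats: FeatureStats,
    inside_counts: dict[str, int],
) -> HeteroGraph:
    """Materialize one tile's heterogeneous graph.

    Nodes are restricted to the padded rectangle (nuclei by polygon
    intersection, with features always computed from the full polygon and
    slide-wide interior counts so duplicated boundary nuclei look identical
    in every tile). A flag marks core vs margin transcripts.
    """
    x = transcripts["x"].to_numpy()
    y = transcripts["y"].to_numpy()
    in_pad = plan.padded_mask(x, y, tile_index)
    sub = transcripts[in_pad].reset_index(drop=True)
    is_core = plan.core_mask(sub["x"].to_numpy(), sub["y"].to_numpy(), tile_index)

    frame = box(*tile.padded)
    keep_ids = [cid for cid, p in nuclei.polygons.items() if p.intersects(frame)]
    sub_nuclei = BoundarySet({cid: nuclei.polygons[cid] for cid in keep_ids}, kind=nuclei.kind)

    t_feat = embedding.rows(sub["gene"].to_numpy(), missing=cfg.missing_gene)
    gene_index = embedding.index()
    t_gene_idx = np.array([gene_index.get(g, -1) for g in sub["gene"]], dtype=np.int64)
    raw_feat = geom_feature_table(sub_nuclei, inside_counts)
    c_feat = feat_stats.apply(raw_feat)
    c_radius = np.sqrt(raw_feat[:, 0] / np.pi) if len(raw_feat) else np.empty(0)
    centroids = (
        np.array([[p.centroid.x, p.centroid.y] for p in sub_nuclei.polygons.values()])
        if len(sub_nuclei) else np.empty((0, 2))
    )

    overlap = label_by_overlap(sub, sub_nuclei)
    tt_src, tt_dst, tt_dist = knn_tt_edges(sub, k=cfg.k_tt, max_dist=cfg.tt_max_dist, z_scale=cfg.z_scale)
    tc_t, tc_c, tc_dist, tc_pdist, tc_label = candidate_tc_edges(
        sub, sub_nuclei, overlap, k_cells=cfg.k_cells, max_dist=cfg.tc_max_dist
    )

    g = HeteroGraph(
        transcript_ids=sub["transcript_id"].to_numpy(),
        t_pos=np.column_stack([sub["x"], sub["y"], sub["z"]]),
        t_feat=t_feat,
        t_gene_idx=t_gene_idx,
        is_core=is_core,
        cell_ids=np.asarray(keep_ids, dtype=object),
        c_feat=c_feat,
        c_centroid=centroids,
        c_radius=c_radius,
        tt_src=tt_src,
        tt_dst=tt_dst,
        tt_dist=tt_dist,
        tc_t=tc_t,
        tc_c=tc_c,
        tc_dist=tc_dist,
        tc_pdist=tc_pdist,
        tc_label=tc_label,
    )
    return g


def build_dataset(
    transcripts: pd.DataFrame,
    nuclei: BoundarySet,
    embedding: GeneEmbedding,
    cfg: GraphConfig | None = None,
    feat_stats: FeatureStats | None = None,
) -> tuple[TilePlan, list[HeteroGraph], FeatureStats]:
    """Tile the extent and build one graph per tile.

    Interior transcript counts and feature standardization statistics are
    computed slide-wide, so identical nuclei get identical features in
    every tile that duplicates them.
    """
    cfg = cfg or GraphConfig()
    # canonical order: id-sorted rows make kNN tie-breaking and tiling
    # independent of input row order
    transcripts = transcripts.sort_values("transcript_id").reset_index(drop=True)
    plan = plan_tiles(transcripts, tile_target=cfg.tile_target, margin=cfg.effective_margin)
    overlap_all = label_by_overlap(transcripts, nuclei)
    inside_counts = overlap_all.dropna().value_counts().to_dict()
    raw_feats = geom_feature_table(nuclei, inside_counts)
    if feat_stats is None:
        feat_stats = compute_feature_stats(raw_feats)
    graphs = [
        build_tile_graph(tile, plan, i, transcripts, nuclei, embedding, cfg, feat_stats, inside_counts)
        for i, tile in enumerate(plan.tiles)
    ]
    return plan, graphs, feat_stats
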