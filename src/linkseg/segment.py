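"""From edge scores to a slide-level segmentation.

Each transcript takes its best-scoring candidate cell if that score clears
the assignment threshold; transcripts assigned to no cell are grouped into
*fragments* — connected components of a graph gated on both spatial
proximity and latent-space (molecular) similarity — and fragments are kept
as entities distinct from cells, never merged with them. Tiled runs are
stitched by keeping each transcript's record from the single tile where it
is core, which together with the receptive-field-wide margin makes tiling
invisible in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .graph import GraphConfig, HeteroGraph, TilePlan, build_dataset
from .io import UNASSIGNED, BoundarySet, SegmentationResult
from .model import TrainedModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssignmentPolicy:
    """Decision rules applied on top of the model's link probabilities."""

    score_threshold: float = 0.5
    margin_rule: str = "core_only"
    fragment_min_size: int = 5
    fragment_link_dist: float = 5.0
    fragment_sim_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0, 1]")
        if self.fragment_min_size < 1:
            raise ValueError("fragment_min_size must be >= 1")
        if self.margin_rule != "core_only":
            raise ValueError("only the core_only margin rule is implemented")


@dataclass
class Fragment:
    fragment_id: str
    members: list[str]
    centroid: tuple[float, float]
    size: int = 0

    def __post_init__(self) -> None:
        self.size = len(self.members)


def assign_transcripts(
    graph: HeteroGraph, scores: np.ndarray, policy: AssignmentPolicy
) -> pd.DataFrame:
    """Argmax-above-threshold assignment of transcripts to candidate cells.

    Exact score ties break toward the smaller cell id; transcripts whose
    best candidate falls below the threshold (or that have no candidate
    edge at all) come back UNASSIGNED with a NaN score.
    """
    base = pd.DataFrame(
        {
            "transcript_id": graph.transcript_ids,
            "assignment": UNASSIGNED,
            "score": np.nan,
            "source": "none",
        }
    )
    if len(graph.tc_t) == 0:
        return base
    edges = pd.DataFrame(
        {
            "t": graph.tc_t,
            "cell": graph.cell_ids[graph.tc_c],
            "score": scores,
        }
    )
    best = (
        edges.sort_values(["t", "score", "cell"], ascending=[True, False, True])
        .drop_duplicates("t", keep="first")
    )
    best = best[best["score"] >= policy.score_threshold]
    base.loc[best["t"].to_numpy(), "assignment"] = best["cell"].to_numpy()
    base.loc[best["t"].to_numpy(), "score"] = best["score"].to_numpy()
    base.loc[best["t"].to_numpy(), "source"] = "model"
    return base


def group_fragments(
    unassigned: pd.DataFrame,
    latents: np.ndarray,
    policy: AssignmentPolicy,
) -> tuple[pd.Series, list[Fragment]]:
    """Cluster unassigned transcripts into spatially and molecularly
    coherent fragments.

    An edge joins two unassigned transcripts when their spatial distance is
    at most ``fragment_link_dist`` AND the cosine similarity of their model
    latents is at least ``fragment_sim_threshold``; fragments are the
    connected components with at least ``fragment_min_size`` members.
    Fragment ids are deterministic, ordered by smallest member transcript id.

    Returns (transcript_id -> fragment_id for fragment members, fragments).
    """
    n = len(unassigned)
    if n == 0:
        return pd.Series(dtype=object), []
    unassigned = unassigned.reset_index(drop=True)
    X = unassigned[["x", "y", "z"]].to_numpy(dtype=float)
    tree = cKDTree(X)
    pairs = tree.query_pairs(r=policy.fragment_link_dist, output_type="ndarray")
    if len(pairs):
        norms = np.linalg.norm(latents, axis=1)
        norms = np.where(norms > 0, norms, 1.0)
        unit = latents / norms[:, None]
        sim = np.einsum("ij,ij->i", unit[pairs[:, 0]], unit[pairs[:, 1]])
        pairs = pairs[sim >= policy.fragment_sim_threshold]
    adj = scipy.sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    tids = unassigned["transcript_id"].to_numpy()

    members: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        members.setdefault(int(lab), []).append(i)
    big = [idxs for idxs in members.values() if len(idxs) >= policy.fragment_min_size]
    big.sort(key=lambda idxs: min(tids[i] for i in idxs))

    mapping: dict[str, str] = {}
    fragments: list[Fragment] = []
    for rank, idxs in enumerate(big):
        fid = f"frag_{rank:06d}"
        ids = sorted(tids[i] for i in idxs)
        centroid = (float(X[idxs, 0].mean()), float(X[idxs, 1].mean()))
        fragments.append(Fragment(fragment_id=fid, members=ids, centroid=centroid))
        for t in ids:
            mapping[t] = fid
    return pd.Series(mapping, dtype=object), fragments


def stitch_tiles(per_tile: list[pd.DataFrame], plan: TilePlan) -> pd.DataFrame:
    """Keep each transcript's record from the tile where it is core."""
    cores = [df[df["is_core"]] for df in per_tile]
    merged = pd.concat(cores, ignore_index=True) if cores else pd.DataFrame()
    if len(merged) and merged["transcript_id"].duplicated().any():
        dup = merged.loc[merged["transcript_id"].duplicated(), "transcript_id"]
        raise RuntimeError(f"transcripts core in multiple tiles: {sorted(set(dup))[:5]}")
    return merged.drop(columns=["is_core"]).sort_values("transcript_id").reset_index(drop=True)


def assignment_rate_curve(max_scores: np.ndarray, thresholds: np.ndarray | None = None) -> dict:
    """Fraction of transcripts that would be cell-assigned at each threshold."""
    thresholds = thresholds if thresholds is not None else np.round(np.arange(0.1, 1.0, 0.1), 1)
    if len(max_scores) == 0:
        return {float(t): 0.0 for t in thresholds}
    return {float(t): float(np.mean(max_scores >= t)) for t in thresholds}


def segment_dataset(
    transcripts: pd.DataFrame,
    nuclei: BoundarySet,
    model: TrainedModel,
    policy: AssignmentPolicy | None = None,
    graph_cfg: GraphConfig | None = None,
    provenance: dict | None = None,
) -> tuple[SegmentationResult, dict]:
    """End-to-end inference: tile, build graphs, score, assign, stitch,
    group leftovers into fragments slide-wide.

    Returns the segmentation plus a run report with assignment counts,
    per-entity medians and the assignment-rate-vs-threshold curve.
    """
    policy = policy or AssignmentPolicy()
    graph_cfg = graph_cfg or model.graph_config
    empty_report = {
        "n_transcripts": 0, "n_cell_assigned": 0, "n_fragment": 0, "n_unassigned": 0,
        "n_cells": 0, "n_fragments": 0, "median_transcripts_per_cell": float("nan"),
        "median_transcripts_per_fragment": float("nan"), "assignment_rate_curve": {},
    }
    if transcripts.empty:
        rows = pd.DataFrame(columns=["transcript_id", "assignment", "score", "source"])
        return SegmentationResult(rows=rows, provenance=provenance or {}), empty_report

    plan, graphs, _ = build_dataset(
        transcripts, nuclei, model.embedding, graph_cfg, feat_stats=model.feat_stats
    )
    per_tile = []
    latent_blocks = []
    max_score_blocks = []
    for g in graphs:
        scores, h_t = model.predict(g)
        df = assign_transcripts(g, scores, policy)
        df["is_core"] = g.is_core
        per_tile.append(df)
        latent_blocks.append(
            pd.DataFrame(h_t[g.is_core], index=g.transcript_ids[g.is_core])
        )
        if len(g.tc_t):
            per_t = pd.Series(scores).groupby(g.tc_t).max()
            core_idx = np.nonzero(g.is_core)[0]
            max_score_blocks.append(per_t.reindex(core_idx).fillna(0.0).to_numpy())
        else:
            max_score_blocks.append(np.zeros(int(g.is_core.sum())))

    stitched = stitch_tiles(per_tile, plan)
    if len(stitched) != len(transcripts):
        raise RuntimeError("stitching lost or duplicated transcripts")
    latents = pd.concat(latent_blocks).sort_index()

    un_mask = stitched["assignment"] == UNASSIGNED
    un = stitched[un_mask].merge(
        transcripts[["transcript_id", "x", "y", "z"]], on="transcript_id"
    )
    frag_map, fragments = group_fragments(
        un, latents.loc[un["transcript_id"].to_numpy()].to_numpy(), policy
    )
    if len(frag_map):
        hit = stitched["transcript_id"].map(frag_map)
        sel = hit.notna()
        stitched.loc[sel, "assignment"] = hit[sel]
        stitched.loc[sel, "source"] = "fragment"

    result = SegmentationResult(rows=stitched, provenance=provenance or {})
    rows = result.rows
    cell_counts = rows[rows["source"] == "model"].groupby("assignment").size()
    frag_counts = rows[rows["source"] == "fragment"].groupby("assignment").size()
    report = {
        "n_transcripts": int(len(rows)),
        "n_cell_assigned": int((rows["source"] == "model").sum()),
        "n_fragment": int((rows["source"] == "fragment").sum()),
        "n_unassigned": int((rows["source"] == "none").sum()),
        "n_cells": int(len(cell_counts)),
        "n_fragments": int(len(frag_counts)),
        "median_transcripts_per_cell": float(cell_counts.median()) if len(cell_counts) else float("nan"),
        "median_transcripts_per_fragment": float(frag_counts.median()) if len(frag_counts) else float("nan"),
        "assignment_rate_curve": assignment_rate_curve(np.concatenate(max_score_blocks)),
        "n_tiles": len(plan.tiles),
    }
    return result, report
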