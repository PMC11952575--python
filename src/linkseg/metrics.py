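"""Evaluation statistics for segmentation quality.

Positive marker purity (PMP) is a per-cell true-positive-rate proxy: among
a cell's transcripts that are markers of any annotated cell type, the
fraction belonging to the cell's own type. The mutually exclusive
co-expression rate (MECR) is a false-positive proxy: for a gene pair
essentially never co-expressed in a matched single-cell reference, the
fraction of segmented cells detecting both genes among cells detecting at
least one. Synthetic tissue additionally provides exact ground truth for
transcript-level precision/recall via greedy largest-overlap matching of
predicted to true cells, and a nearest-nucleus baseline for comparison.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.strtree import STRtree

from .io import UNASSIGNED, BoundarySet, SegmentationResult, cell_gene_counts

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    n_cells: int = 0
    n_fragments: int = 0
    median_area: float | None = None
    median_counts_per_cell: float = float("nan")
    median_counts_per_fragment: float = float("nan")
    pmp_per_cell: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    mecr_per_pair: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None

    def to_dict(self) -> dict:
        out = {
            "n_cells": self.n_cells,
            "n_fragments": self.n_fragments,
            "median_counts_per_cell": self.median_counts_per_cell,
            "median_counts_per_fragment": self.median_counts_per_fragment,
            "mean_pmp": float(self.pmp_per_cell.mean()) if len(self.pmp_per_cell) else None,
            "mean_mecr": float(self.mecr_per_pair.mean()) if len(self.mecr_per_pair) else None,
        }
        if self.median_area is not None:
            out["median_area"] = self.median_area
        for k in ("precision", "recall", "f1"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        return out


def positive_marker_purity(
    cell_counts: pd.DataFrame,
    cell_type: pd.Series | dict,
    markers: dict[str, set[str]],
) -> tuple[pd.Series, list[str]]:
    """Per-cell positive marker purity.

    PMP(cell) = (counts of the cell's own type's markers) / (counts of
    markers of any type). Cells with zero marker transcripts are excluded
    and returned separately. Raises if any cell lacks a type annotation or
    marker sets overlap.
    """
    cell_type = pd.Series(cell_type)
    union: set[str] = set().union(*markers.values()) if markers else set()
    all_markers = sorted(union)
    if sum(len(m) for m in markers.values()) != len(union):
        raise ValueError("marker sets must be disjoint across cell types")
    missing = [c for c in cell_counts.index if c not in cell_type.index]
    if missing:
        raise ValueError(f"cells without a type annotation: {missing[:5]}")

    present = [g for g in all_markers if g in cell_counts.columns]
    marker_counts = cell_counts[present] if present else cell_counts.iloc[:, :0]
    total = marker_counts.sum(axis=1)
    pmp = {}
    excluded = []
    for cell in cell_counts.index:
        if total.get(cell, 0) == 0:
            excluded.append(cell)
            continue
        own = markers.get(cell_type[cell], set())
        own_present = [g for g in own if g in cell_counts.columns]
        own_count = cell_counts.loc[cell, own_present].sum() if own_present else 0
        pmp[cell] = float(own_count) / float(total[cell])
    if excluded:
        logger.info("%d cells with zero marker counts excluded from PMP", len(excluded))
    return pd.Series(pmp, dtype=float), excluded


def _codetection_rates(counts: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.Series:
    detected = counts > 0
    rates = {}
    for g1, g2 in pairs:
        both = (detected[g1] & detected[g2]).sum()
        either = (detected[g1] | detected[g2]).sum()
        rates[(g1, g2)] = float(both) / float(either) if either else float("nan")
    return pd.Series(rates, dtype=float)


def select_exclusive_pairs(
    ref_counts: pd.DataFrame, codetect_max: float = 0.01
) -> list[tuple[str, str]]:
    """Unordered gene pairs whose codetection rate in the reference cells is
    strictly below ``codetect_max`` (cells with both > 0 over cells with at
    least one > 0), in lexicographic order."""
    genes = sorted(ref_counts.columns)
    pairs = list(itertools.combinations(genes, 2))
    rates = _codetection_rates(ref_counts, pairs)
    return [p for p in pairs if not np.isnan(rates[p]) and rates[p] < codetect_max]


def mecr(cell_counts: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.Series:
    """Mutually exclusive co-expression rate per gene pair.

    MECR(g1, g2) = #cells detecting both / #cells detecting either; pairs
    detected in no cell are NaN (undefined) and excluded from summaries.
    """
    unknown = [p for p in pairs if p[0] not in cell_counts.columns or p[1] not in cell_counts.columns]
    if unknown:
        raise ValueError(f"pairs reference unmeasured genes: {unknown[:5]}")
    return _codetection_rates(cell_counts, pairs)


def summary_stats(
    result: SegmentationResult,
    transcripts: pd.DataFrame,
    boundaries: BoundarySet | None = None,
    min_counts: int = 5,
) -> MetricsReport:
    """Counts and medians over cells passing the minimum-count filter.

    Cells (model-assigned) and fragments are summarized separately; median
    polygon area is included only when boundaries are supplied.
    """
    counts = cell_gene_counts(result, transcripts, min_counts=min_counts)
    totals = counts.sum(axis=1) if len(counts) else pd.Series(dtype=float)
    sources = result.rows.drop_duplicates("assignment").set_index("assignment")["source"]
    is_frag = pd.Series(
        [sources.get(c) == "fragment" for c in totals.index], index=totals.index, dtype=bool
    )
    cell_totals = totals[~is_frag]
    frag_totals = totals[is_frag]
    report = MetricsReport(
        n_cells=int(len(cell_totals)),
        n_fragments=int(len(frag_totals)),
        median_counts_per_cell=float(cell_totals.median()) if len(cell_totals) else float("nan"),
        median_counts_per_fragment=float(frag_totals.median()) if len(frag_totals) else float("nan"),
    )
    if boundaries is not None:
        areas = [boundaries.polygons[c].area for c in cell_totals.index if c in boundaries.polygons]
        report.median_area = float(np.median(areas)) if areas else None
    return report


def greedy_match(overlap: pd.DataFrame) -> dict[str, str]:
    """Greedy largest-overlap matching of predicted to true cells.

    ``overlap`` is predicted x true shared-transcript counts. Pairs are
    taken in decreasing overlap (ties broken lexicographically), each
    predicted and each true cell used at most once.
    """
    entries = [
        (int(overlap.iat[i, j]), str(overlap.index[i]), str(overlap.columns[j]))
        for i in range(overlap.shape[0])
        for j in range(overlap.shape[1])
        if overlap.iat[i, j] > 0
    ]
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    used_pred: set[str] = set()
    used_true: set[str] = set()
    matching: dict[str, str] = {}
    for _, pred, true in entries:
        if pred in used_pred or true in used_true:
            continue
        matching[pred] = true
        used_pred.add(pred)
        used_true.add(true)
    return matching


def assignment_prf(
    result: SegmentationResult, true_assignment: pd.Series
) -> tuple[float, float, float]:
    """Transcript-level precision/recall/F1 against synthetic ground truth.

    Predicted cells are matched to true cells greedily by largest overlap;
    a transcript counts as a true positive iff it is model-assigned to the
    predicted cell matched to its true source cell. Precision is TP over
    assigned transcripts (0, flagged, when nothing is assigned), recall TP
    over all transcripts.
    """
    rows = result.rows
    assigned = rows[rows["source"] == "model"].copy()
    n_total = len(rows)
    if len(assigned) == 0:
        logger.warning("no transcripts assigned; precision reported as 0 by convention")
        return 0.0, 0.0, 0.0
    assigned["true"] = true_assignment.reindex(assigned["transcript_id"].to_numpy()).to_numpy()
    overlap = assigned.groupby(["assignment", "true"]).size().unstack(fill_value=0)
    matching = greedy_match(overlap)
    tp = int(
        sum(
            int(overlap.loc[pred, true])
            for pred, true in matching.items()
            if true in overlap.columns
        )
    )
    precision = tp / len(assigned)
    recall = tp / n_total if n_total else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return float(precision), float(recall), float(f1)


def nearest_nucleus_assignment(
    transcripts: pd.DataFrame, nuclei: BoundarySet, radius: float = 15.0
) -> SegmentationResult:
    """Baseline segmentation: each transcript joins the nucleus whose
    outline is nearest in the plane, if within ``radius`` micrometers.

    This is the expansion-style heuristic the model is benchmarked against.
    """
    ids = list(nuclei.polygons)
    rows = pd.DataFrame(
        {
            "transcript_id": transcripts["transcript_id"].to_numpy(),
            "assignment": UNASSIGNED,
            "score": np.nan,
            "source": "none",
        }
    )
    if ids and len(transcripts):
        polys = list(nuclei.polygons.values())
        tree = STRtree(polys)
        pts = shapely.points(transcripts["x"].to_numpy(), transcripts["y"].to_numpy())
        nearest = tree.query_nearest(pts, max_distance=radius, all_matches=False)
        ti, ni = nearest
        dist = shapely.distance(pts[ti], np.array(polys, dtype=object)[ni])
        keep = dist <= radius
        rows.loc[ti[keep], "assignment"] = [ids[j] for j in ni[keep]]
        rows.loc[ti[keep], "source"] = "model"
        rows.loc[ti[keep], "score"] = 1.0
    return SegmentationResult(rows=rows, provenance={"method": "nearest_nucleus", "radius": radius})
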