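"""Readers and writers for on-disk artifacts.

Transcript tables and boundary vertex lists follow the column conventions of
imaging-based spatial transcriptomics platforms (Xenium-style names are
accepted through an alias map), boundaries may alternatively come as GeoJSON
polygons, and reference expression matrices are CSV or MatrixMarket with
side-car name files. Segmentation results round-trip through plain CSV and
cell-by-gene count matrices are written as MatrixMarket.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

#: sentinel assignment for transcripts attached to neither a cell nor a fragment
UNASSIGNED = "UNASSIGNED"

#: canonical column name -> accepted aliases (first match wins)
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "transcript_id": ("transcript_id", "id"),
    "gene": ("gene", "feature_name"),
    "x": ("x", "x_location"),
    "y": ("y", "y_location"),
    "z": ("z", "z_location"),
    "quality": ("quality", "qv"),
    "prior_cell_id": ("prior_cell_id", "cell_id"),
}


class FormatError(ValueError):
    """A file is structurally unusable (missing columns, dimension mismatch)."""


class ValidationError(ValueError):
    """A file parses but violates a content invariant (duplicates, bad geometry)."""


@dataclass
class BoundarySet:
    """Staining-derived nucleus or cell outlines keyed by cell id.

    ``polygons`` maps cell_id to a closed, simple shapely Polygon with
    positive area; ``kind`` records whether the outlines trace nuclei or
    whole cells.
    """

    polygons: dict[str, Polygon]
    kind: str = "nucleus"

    def __post_init__(self) -> None:
        if self.kind not in ("nucleus", "cell"):
            raise ValueError(f"kind must be 'nucleus' or 'cell', got {self.kind!r}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.polygons)

    def centroids(self) -> pd.DataFrame:
        rows = [(cid, p.centroid.x, p.centroid.y) for cid, p in self.polygons.items()]
        return pd.DataFrame(rows, columns=["cell_id", "x", "y"]).set_index("cell_id")

    def __len__(self) -> int:
        return len(self.polygons)


@dataclass
class ReferenceMatrix:
    """Mean expression per gene per cell type, standing in for an scRNA-seq atlas.

    ``mean_expr`` is genes x cell_types, nonnegative, library-size normalized
    (columns need not sum to one after subsetting). ``markers`` holds, per
    cell type, the genes confidently specific to it; marker sets are disjoint
    across types by construction.
    """

    genes: list[str]
    cell_types: list[str]
    mean_expr: np.ndarray
    markers: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean_expr = np.asarray(self.mean_expr, dtype=float)
        if self.mean_expr.shape != (len(self.genes), len(self.cell_types)):
            raise FormatError(
                f"mean_expr shape {self.mean_expr.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cell_types)} cell types"
            )
        if (self.mean_expr < 0).any():
            raise ValidationError("mean_expr must be nonnegative")

    def profile(self, cell_type: str) -> np.ndarray:
        """Column of ``mean_expr`` normalized to sum to one."""
        col = self.mean_expr[:, self.cell_types.index(cell_type)].astype(float)
        total = col.sum()
        if total <= 0:
            raise ValidationError(f"cell type {cell_type!r} has all-zero expression")
        return col / total


@dataclass
class SegmentationResult:
    """Per-transcript assignment with provenance.

    ``rows`` has columns transcript_id, assignment (a cell id, a fragment id,
    or UNASSIGNED), score (model link probability; NaN unless source is
    'model') and source in {'model', 'fragment', 'none'}.
    """

    rows: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["transcript_id", "assignment", "score", "source"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise FormatError(f"segmentation rows missing columns: {missing}")
        if self.rows["transcript_id"].duplicated().any():
            dup = self.rows.loc[self.rows["transcript_id"].duplicated(), "transcript_id"]
            raise ValidationError(f"duplicate transcript ids: {sorted(set(dup))[:5]}")
        self.rows = (
            self.rows[required].sort_values("transcript_id").reset_index(drop=True)
        )

    def assigned_mask(self) -> pd.Series:
        return self.rows["source"] == "model"

    def counts_by_assignment(self) -> pd.Series:
        kept = self.rows[self.rows["assignment"] != UNASSIGNED]
        return kept.groupby("assignment").size()


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix in (".parquet", ".pq"):
        return pd.read_parquet(path)
    return pd.read_csv(path)


def _apply_aliases(df: pd.DataFrame, aliases: dict[str, tuple[str, ...]]) -> pd.DataFrame:
    rename = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in df.columns:
                rename[name] = canonical
                break
    return df.rename(columns=rename)


def read_transcripts(
    path: str | Path,
    min_quality: float = 20.0,
    aliases: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Read a transcript point table, dropping low-quality detections.

    Parameters
    ----------
    path
        CSV or parquet file with columns mappable to (transcript_id, gene,
        x, y[, z], quality[, prior_cell_id]) through the alias map.
    min_quality
        Phred-like threshold; rows with quality strictly below it are dropped.
    aliases
        Optional override of :data:`DEFAULT_ALIASES`.

    Returns
    -------
    DataFrame sorted by transcript_id with canonical columns; z defaults to 0
    and prior_cell_id to NA when absent from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _apply_aliases(_read_table(path), aliases or DEFAULT_ALIASES)
    for col in ("transcript_id", "gene", "x", "y", "quality"):
        if col not in df.columns:
            raise FormatError(f"transcript table {path} lacks a {col!r} column")
    if "z" not in df.columns:
        df["z"] = 0.0
    if "prior_cell_id" not in df.columns:
        df["prior_cell_id"] = pd.NA
    df = df[["transcript_id", "gene", "x", "y", "z", "quality", "prior_cell_id"]].copy()
    df["transcript_id"] = df["transcript_id"].astype(str)
    df["gene"] = df["gene"].astype(str)
    for col in ("x", "y", "z", "quality"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)

    if df["transcript_id"].duplicated().any():
        dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"]
        raise ValidationError(f"duplicate transcript_id values: {sorted(set(dup))[:5]}")
    if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
        raise ValidationError("non-finite coordinates in transcript table")
    if (df["gene"] == "").any():
        raise ValidationError("empty gene names in transcript table")
    if (df["quality"] < 0).any():
        raise ValidationError("negative quality scores in transcript table")

    n_before = len(df)
    df = df[df["quality"] >= min_quality]
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d/%d transcripts below quality %g", n_dropped, n_before, min_quality)
    return df.sort_values("transcript_id").reset_index(drop=True)


def _validate_polygon(cell_id: str, coords: np.ndarray) -> Polygon:
    if len(np.unique(coords, axis=0)) < 3:
        raise ValidationError(f"polygon {cell_id!r} has fewer than 3 distinct vertices")
    poly = Polygon(coords)
    if not poly.is_valid:
        raise ValidationError(f"polygon {cell_id!r} is self-intersecting or otherwise invalid")
    if poly.area <= 0:
        raise ValidationError(f"polygon {cell_id!r} has zero area")
    return poly


def read_boundaries(path: str | Path, kind: str = "nucleus") -> BoundarySet:
    """Read nucleus or cell outlines from a vertex-list table or GeoJSON.

    Vertex-list form needs columns (cell_id, vertex_x, vertex_y) with
    vertices in file order; GeoJSON must be a FeatureCollection of Polygons
    with a cell_id (or id) property. Degenerate or self-intersecting polygons
    raise :class:`ValidationError` naming the offending cell ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    polygons: dict[str, Polygon] = {}
    bad: list[str] = []
    if path.suffix in (".geojson", ".json"):
        payload = json.loads(path.read_text())
        features = payload.get("features", [])
        for i, feat in enumerate(features):
            props = feat.get("properties") or {}
            cid = str(props.get("cell_id", props.get("id", feat.get("id", i))))
            geom = feat.get("geometry", {})
            if geom.get("type") != "Polygon":
                raise FormatError(f"feature {cid!r} is not a Polygon")
            coords = np.asarray(geom["coordinates"][0], dtype=float)
            try:
                polygons[cid] = _validate_polygon(cid, coords)
            except ValidationError:
                bad.append(cid)
    else:
        df = _read_table(path)
        for col in ("cell_id", "vertex_x", "vertex_y"):
            if col not in df.columns:
                raise FormatError(f"boundary table {path} lacks a {col!r} column")
        for cid, grp in df.groupby("cell_id", sort=True):
            cid = str(cid)
            coords = grp[["vertex_x", "vertex_y"]].to_numpy(dtype=float)
            try:
                polygons[cid] = _validate_polygon(cid, coords)
            except ValidationError:
                bad.append(cid)
    if bad:
        raise ValidationError(f"degenerate or invalid polygons for cell ids: {sorted(bad)}")
    return BoundarySet(polygons=polygons, kind=kind)


def write_boundaries(boundaries: BoundarySet, path: str | Path) -> None:
    """Write a boundary set as a (cell_id, vertex_x, vertex_y) CSV."""
    records = []
    for cid, poly in boundaries.polygons.items():
        xs, ys = poly.exterior.coords.xy
        # shapely closes rings; drop the repeated last vertex
        for x, y in zip(xs[:-1], ys[:-1]):
            records.append((cid, x, y))
    pd.DataFrame(records, columns=["cell_id", "vertex_x", "vertex_y"]).to_csv(path, index=False)


def derive_markers(
    genes: list[str],
    cell_types: list[str],
    mean_expr: np.ndarray,
    fold_change: float = 2.0,
    min_expr: float = 1e-9,
) -> dict[str, set[str]]:
    """Markers of a type: genes whose mean expression there exceeds
    ``fold_change`` times their mean in every other type (strictly, so exact
    ties are excluded) and clears the ``min_expr`` floor."""
    markers: dict[str, set[str]] = {t: set() for t in cell_types}
    expr = np.asarray(mean_expr, dtype=float)
    for j, ctype in enumerate(cell_types):
        own = expr[:, j]
        others = np.delete(expr, j, axis=1)
        if others.shape[1] == 0:
            continue
        ok = (own >= min_expr) & (own > fold_change * others.max(axis=1))
        markers[ctype] = {genes[i] for i in np.nonzero(ok)[0]}
    return markers


def read_reference(
    path_matrix: str | Path,
    path_genes: str | Path,
    path_types: str | Path,
    fold_change: float = 2.0,
    min_expr: float = 1e-9,
) -> ReferenceMatrix:
    """Read a gene x cell-type mean-expression matrix plus name files.

    The matrix is CSV (no header) or MatrixMarket; ``path_genes`` and
    ``path_types`` are one name per line and must match the matrix
    dimensions. Markers are derived with :func:`derive_markers`.
    """
    path_matrix = Path(path_matrix)
    genes = [ln.strip() for ln in Path(path_genes).read_text().splitlines() if ln.strip()]
    cell_types = [ln.strip() for ln in Path(path_types).read_text().splitlines() if ln.strip()]
    if path_matrix.suffix == ".mtx":
        mat = scipy.io.mmread(path_matrix)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
    else:
        mat = np.loadtxt(path_matrix, delimiter=",", ndmin=2, dtype=float)
    if mat.shape != (len(genes), len(cell_types)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes x "
            f"{len(cell_types)} cell types"
        )
    markers = derive_markers(genes, cell_types, mat, fold_change=fold_change, min_expr=min_expr)
    return ReferenceMatrix(genes=genes, cell_types=cell_types, mean_expr=mat, markers=markers)


def write_segmentation(result: SegmentationResult, path: str | Path) -> None:
    """Write a segmentation result as CSV, stably sorted by transcript_id."""
    out = result.rows.sort_values("transcript_id")
    out.to_csv(path, index=False, float_format="%.6f")


def read_segmentation(path: str | Path) -> SegmentationResult:
    """Read a segmentation CSV written by :func:`write_segmentation`."""
    df = pd.read_csv(
        path,
        dtype={"transcript_id": str, "assignment": str, "source": str},
    )
    if df.empty and "transcript_id" not in df.columns:
        raise FormatError(f"{path} is not a segmentation CSV")
    df["score"] = pd.to_numeric(df.get("score"), errors="coerce").astype(float)
    return SegmentationResult(rows=df)


def cell_gene_counts(
    result: SegmentationResult,
    transcripts: pd.DataFrame,
    min_counts: int = 5,
) -> pd.DataFrame:
    """Cell-by-gene transcript counts from a segmentation.

    Unassigned transcripts are excluded; cells and fragments whose total
    count falls below ``min_counts`` are discarded. Returns a dense
    DataFrame indexed by assignment id with genes as columns.
    """
    merged = result.rows.merge(
        transcripts[["transcript_id", "gene"]], on="transcript_id", how="left"
    )
    if merged["gene"].isna().any():
        missing = merged.loc[merged["gene"].isna(), "transcript_id"]
        raise ValidationError(f"assignments reference unknown transcripts: {list(missing[:5])}")
    merged = merged[merged["assignment"] != UNASSIGNED]
    if merged.empty:
        return pd.DataFrame(dtype=int)
    counts = merged.groupby(["assignment", "gene"]).size().unstack(fill_value=0)
    counts = counts[counts.sum(axis=1) >= min_counts]
    return counts


def write_cell_matrix(
    result: SegmentationResult,
    transcripts: pd.DataFrame,
    path: str | Path,
    min_counts: int = 5,
) -> None:
    """Write the cell-by-gene count matrix as MatrixMarket plus name files.

    ``path`` is the .mtx file; ``<stem>.cells.txt`` and ``<stem>.genes.txt``
    are written next to it. Cells (and fragments) totaling fewer than
    ``min_counts`` transcripts are omitted, matching the minimum-count filter
    applied before any per-cell summary.
    """
    path = Path(path)
    counts = cell_gene_counts(result, transcripts, min_counts=min_counts)
    if counts.empty:
        mat = scipy.sparse.csr_matrix((0, 0), dtype=np.int64)
        cells: list[str] = []
        genes: list[str] = []
    else:
        mat = scipy.sparse.csr_matrix(counts.to_numpy(dtype=np.int64))
        cells = list(counts.index)
        genes = list(counts.columns)
    scipy.io.mmwrite(str(path), mat)
    path.with_suffix(".cells.txt").write_text("".join(c + "\n" for c in cells))
    path.with_suffix(".genes.txt").write_text("".join(g + "\n" for g in genes))
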