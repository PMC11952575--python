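import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Point, Polygon

from linkseg.graph import (
    GraphConfig,
    build_dataset,
    candidate_tc_edges,
    cell_geom_features,
    knn_tt_edges,
    label_by_overlap,
    plan_tiles,
)
from linkseg.io import BoundarySet


def _transcripts(points, ids=None):
    points = np.asarray(points, dtype=float)
    if points.shape[1] == 2:
        points = np.column_stack([points, np.zeros(len(points))])
    ids = ids or [f"t{i:03d}" for i in range(len(points))]
    return pd.DataFrame(
        {
            "transcript_id": ids,
            "gene": "g0",
            "x": points[:, 0],
            "y": points[:, 1],
            "z": points[:, 2],
            "quality": 40.0,
            "prior_cell_id": pd.NA,
        }
    )


def brute_force_knn(points, k, max_dist, z_scale=1.0):
    """All-pairs oracle with the same (distance, smaller-id) tie rule."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    pts = pts * np.array([1.0, 1.0, z_scale])
    n = len(pts)
    undirected = set()
    for i in range(n):
        d = np.linalg.norm(pts - pts[i], axis=1)
        order = sorted((float(d[j]), j) for j in range(n) if j != i)
        taken = 0
        for dist, j in order:
            if dist > max_dist or taken == k:
                break
            undirected.add((min(i, j), max(i, j)))
            taken += 1
    return undirected


class TestKnnEdges:
    def test_three_collinear_points(self):
        tr = _transcripts([[0, 0], [1, 0], [3, 0]])
        src, dst, dist = knn_tt_edges(tr, k=1, max_dist=np.inf)
        edges = set(zip(src.tolist(), dst.tolist()))
        assert edges == {(0, 1), (1, 0), (1, 2), (2, 1)}

    def test_complete_graph_when_k_large(self):
        tr = _transcripts(np.random.default_rng(0).uniform(0, 10, (6, 2)))
        src, dst, _ = knn_tt_edges(tr, k=10, max_dist=np.inf)
        assert len(src) == 6 * 5

    def test_zero_max_dist_empty(self):
        tr = _transcripts([[0, 0], [1, 0]])
        src, _, _ = knn_tt_edges(tr, k=1, max_dist=0.0)
        assert len(src) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 30, size=(500, 2))
        tr = _transcripts(pts)
        src, dst, dist = knn_tt_edges(tr, k=5, max_dist=5.0)
        got = {(min(a, b), max(a, b)) for a, b in zip(src.tolist(), dst.tolist())}
        assert got == brute_force_knn(pts, k=5, max_dist=5.0)
        # reported distances are exact
        for a, b, d in zip(src, dst, dist):
            assert d == pytest.approx(np.linalg.norm(pts[a] - pts[b]))

    def test_z_scale_changes_metric(self):
        pts = np.array([[0, 0, 0], [0.0, 3.0, 0.0], [0.0, 0.0, 1.0]])
        tr = _transcripts(pts)
        src, dst, _ = knn_tt_edges(tr, k=1, max_dist=np.inf, z_scale=1.0)
        assert (0, 2) in set(zip(src.tolist(), dst.tolist()))
        src, dst, _ = knn_tt_edges(tr, k=1, max_dist=np.inf, z_scale=10.0)
        assert (0, 1) in set(zip(src.tolist(), dst.tolist()))


def _squares(offsets, side=1.0, kind="nucleus"):
    polys = {}
    for i, (x0, y0) in enumerate(offsets):
        polys[f"c{i}"] = Polygon(
            [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]
        )
    return BoundarySet(polygons=polys, kind=kind)


class TestOverlapLabels:
    def test_interior_exterior_and_boundary(self):
        nuclei = _squares([(0, 0)])
        tr = _transcripts([[0.5, 0.5], [2.0, 2.0], [1.0, 0.5]])
        out = label_by_overlap(tr, nuclei)
        assert out.iloc[0] == "c0"
        assert out.iloc[1] is None
        assert out.iloc[2] == "c0"  # on the outline counts as inside

    def test_ambiguous_overlap_maps_to_none(self):
        nuclei = _squares([(0, 0), (0.5, 0.0)])
        tr = _transcripts([[0.75, 0.5]])
        assert label_by_overlap(tr, nuclei).iloc[0] is None

    def test_matches_point_in_polygon_oracle(self, tissue_small):
        overlap = label_by_overlap(tissue_small.transcripts, tissue_small.nuclei)
        rng = np.random.default_rng(0)
        idx = rng.choice(len(tissue_small.transcripts), size=200, replace=False)
        for i in idx:
            row = tissue_small.transcripts.iloc[i]
            covering = [
                cid
                for cid, poly in tissue_small.nuclei.polygons.items()
                if poly.covers(Point(row.x, row.y))
            ]
            expected = covering[0] if len(covering) == 1 else None
            assert overlap.loc[row.transcript_id] == expected or (
                expected is None and overlap.loc[row.transcript_id] is None
            )


class TestCandidateEdges:
    def test_positive_and_negative_labels(self):
        nuclei = _squares([(0, 0), (3, 0)])
        tr = _transcripts([[0.5, 0.5]])
        overlap = label_by_overlap(tr, nuclei)
        t, c, d, pdist, lab = candidate_tc_edges(tr, nuclei, overlap, k_cells=4, max_dist=10.0)
        by_cell = dict(zip(c.tolist(), lab.tolist()))
        assert by_cell == {0: 1, 1: 0}

    def test_no_containing_nucleus_all_unlabeled(self):
        nuclei = _squares([(0, 0)])
        tr = _transcripts([[2.0, 2.0]])
        overlap = label_by_overlap(tr, nuclei)
        *_, lab = candidate_tc_edges(tr, nuclei, overlap, k_cells=4, max_dist=10.0)
        assert (lab == -1).all()

    def test_k_cells_one_keeps_single_positive(self):
        nuclei = _squares([(0, 0), (5, 0)])
        tr = _transcripts([[0.5, 0.5]])
        overlap = label_by_overlap(tr, nuclei)
        t, c, *_, lab = candidate_tc_edges(tr, nuclei, overlap, k_cells=1, max_dist=10.0)
        assert len(t) == 1 and lab[0] == 1

    def test_outline_distance_zero_inside(self):
        nuclei = _squares([(0, 0), (4, 0)])
        tr = _transcripts([[0.5, 0.5]])
        overlap = label_by_overlap(tr, nuclei)
        t, c, d, pdist, lab = candidate_tc_edges(tr, nuclei, overlap, k_cells=4, max_dist=10.0)
        assert pdist[lab == 1][0] == 0.0
        assert pdist[lab == 0][0] == pytest.approx(3.5)


class TestGeomFeatures:
    def test_unit_square_closed_forms(self):
        f = cell_geom_features(Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]))
        area, perim, circ, elong, convex, logn = f
        assert area == pytest.approx(1.0)
        assert perim == pytest.approx(4.0)
        assert circ == pytest.approx(np.pi / 4, abs=1e-12)
        assert elong == pytest.approx(1.0)
        assert convex == pytest.approx(1.0)
        assert logn == 0.0

    def test_circle_circularity_close_to_one(self):
        theta = np.linspace(0, 2 * np.pi, 361)[:-1]
        circle = Polygon(np.column_stack([np.cos(theta), np.sin(theta)]))
        assert cell_geom_features(circle)[2] == pytest.approx(1.0, abs=1e-3)

    def test_rectangle_elongation_is_aspect_ratio(self):
        rect = Polygon([(0, 0), (2, 0), (2, 1), (0, 1)])
        assert cell_geom_features(rect)[3] == pytest.approx(0.5)

    def test_l_shape_convexity_below_one(self):
        l_shape = Polygon([(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)])
        assert cell_geom_features(l_shape)[4] < 1.0

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(Exception):
            cell_geom_features(Polygon())


class TestTilePlan:
    def test_single_tile_when_few_points(self):
        tr = _transcripts(np.random.default_rng(0).uniform(0, 10, (20, 2)))
        plan = plan_tiles(tr, tile_target=100, margin=1.0)
        assert len(plan.tiles) == 1
        assert plan.tiles[0].core == plan.extent

    def test_four_clusters_give_four_tiles(self):
        rng = np.random.default_rng(0)
        clusters = [
            rng.normal(loc, 0.5, size=(25, 2))
            for loc in [(0, 0), (20, 0), (0, 20), (20, 20)]
        ]
        tr = _transcripts(np.vstack(clusters))
        plan = plan_tiles(tr, tile_target=25, margin=1.0)
        assert len(plan.tiles) == 4
        x, y = tr["x"].to_numpy(), tr["y"].to_numpy()
        counts = [int(plan.core_mask(x, y, i).sum()) for i in range(4)]
        assert counts == [25, 25, 25, 25]

    def test_zero_margin_padded_equals_core(self):
        tr = _transcripts(np.random.default_rng(1).uniform(0, 10, (300, 2)))
        plan = plan_tiles(tr, tile_target=100, margin=0.0)
        for tile in plan.tiles:
            assert tile.padded == tile.core

    def test_cores_partition_all_transcripts(self):
        tr = _transcripts(np.random.default_rng(2).uniform(0, 50, (800, 2)))
        plan = plan_tiles(tr, tile_target=120, margin=5.0)
        x, y = tr["x"].to_numpy(), tr["y"].to_numpy()
        membership = np.zeros(len(tr), dtype=int)
        for i in range(len(plan.tiles)):
            membership += plan.core_mask(x, y, i).astype(int)
        assert (membership == 1).all()


class TestBuildDataset:
    def test_interior_transcripts_get_positive_edges(self, tissue_small):
        from linkseg.embeddings import reference_embedding

        emb = reference_embedding(tissue_small.reference, d=3)
        _, graphs, _ = build_dataset(
            tissue_small.transcripts, tissue_small.nuclei, emb, GraphConfig()
        )
        g = graphs[0]
        g.validate()
        assert (g.tc_label == 1).sum() > 0

    def test_positive_edges_inside_polygon_oracle(self, tissue_small):
        from linkseg.embeddings import reference_embedding

        emb = reference_embedding(tissue_small.reference, d=3)
        _, graphs, _ = build_dataset(
            tissue_small.transcripts, tissue_small.nuclei, emb, GraphConfig()
        )
        for g in graphs:
            pos = g.tc_label == 1
            for t_idx, c_idx in zip(g.tc_t[pos], g.tc_c[pos]):
                poly = tissue_small.nuclei.polygons[g.cell_ids[c_idx]]
                assert poly.covers(Point(g.t_pos[t_idx, 0], g.t_pos[t_idx, 1]))

    def test_row_permutation_invariance(self, tissue_small):
        from linkseg.embeddings import reference_embedding

        emb = reference_embedding(tissue_small.reference, d=3)
        cfg = GraphConfig()
        _, graphs_a, _ = build_dataset(
            tissue_small.transcripts, tissue_small.nuclei, emb, cfg
        )
        shuffled = tissue_small.transcripts.sample(frac=1.0, random_state=0)
        _, graphs_b, _ = build_dataset(shuffled, tissue_small.nuclei, emb, cfg)
        for ga, gb in zip(graphs_a, graphs_b):
            np.testing.assert_array_equal(ga.transcript_ids, gb.transcript_ids)
            np.testing.assert_array_equal(ga.tt_src, gb.tt_src)
            np.testing.assert_array_equal(ga.tc_t, gb.tc_t)
            np.testing.assert_array_equal(ga.tc_label, gb.tc_label)

    def test_unknown_gene_raises_by_default(self, tissue_small):
        from linkseg.embeddings import learned_embedding_init

        emb = learned_embedding_init(["only_gene"], d=4, seed=0)
        with pytest.raises(KeyError):
            build_dataset(tissue_small.transcripts, tissue_small.nuclei, emb, GraphConfig())
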