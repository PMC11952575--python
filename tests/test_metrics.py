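import itertools

import numpy as np
import pandas as pd
import pytest

from linkseg.io import UNASSIGNED, SegmentationResult
from linkseg.metrics import (
    assignment_prf,
    greedy_match,
    mecr,
    positive_marker_purity,
    select_exclusive_pairs,
    summary_stats,
)


def _counts(data, genes):
    return pd.DataFrame(data, columns=genes, index=[f"c{i}" for i in range(len(data))])


class TestPMP:
    markers = {"T1": {"m1"}, "T2": {"m2"}}

    def test_hand_enumerated_purity(self):
        counts = _counts([[3, 1, 7]], ["m1", "m2", "other"])
        pmp, excluded = positive_marker_purity(counts, {"c0": "T1"}, self.markers)
        assert pmp["c0"] == pytest.approx(0.75)
        assert excluded == []

    def test_only_own_markers_gives_one(self):
        counts = _counts([[5, 0, 2]], ["m1", "m2", "other"])
        pmp, _ = positive_marker_purity(counts, {"c0": "T1"}, self.markers)
        assert pmp["c0"] == 1.0

    def test_zero_marker_cell_excluded(self):
        counts = _counts([[0, 0, 9]], ["m1", "m2", "other"])
        pmp, excluded = positive_marker_purity(counts, {"c0": "T1"}, self.markers)
        assert "c0" not in pmp.index and excluded == ["c0"]

    def test_missing_type_annotation_raises(self):
        counts = _counts([[1, 0, 0]], ["m1", "m2", "other"])
        with pytest.raises(ValueError, match="c0"):
            positive_marker_purity(counts, {}, self.markers)

    def test_overlapping_marker_sets_rejected(self):
        counts = _counts([[1, 0]], ["m1", "m2"])
        with pytest.raises(ValueError, match="disjoint"):
            positive_marker_purity(counts, {"c0": "T1"}, {"T1": {"m1"}, "T2": {"m1"}})


class TestExclusivePairs:
    def test_never_coexpressed_selected(self):
        counts = _counts([[1, 0], [0, 1]], ["g1", "g2"])
        assert select_exclusive_pairs(counts, 0.01) == [("g1", "g2")]

    def test_always_coexpressed_excluded(self):
        counts = _counts([[1, 1], [2, 3]], ["g1", "g2"])
        assert select_exclusive_pairs(counts, 0.01) == []

    def test_four_gene_toy_hand_enumerated(self):
        # cells: c0 has g1 only, c1 has g2 only, c2 has both g1+g2, c3 has g3+g4
        counts = _counts(
            [[1, 0, 0, 0], [0, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
            ["g1", "g2", "g3", "g4"],
        )
        # rate(g1,g2) = 1/3; with codetect_max 0.5 it is selected, with 0.2 not
        assert ("g1", "g2") in select_exclusive_pairs(counts, 0.5)
        assert ("g1", "g2") not in select_exclusive_pairs(counts, 0.2)
        # order is lexicographic
        pairs = select_exclusive_pairs(counts, 0.5)
        assert pairs == sorted(pairs)


class TestMECR:
    def test_one_third_from_enumeration(self):
        counts = _counts([[2, 0], [0, 1], [3, 4]], ["g1", "g2"])
        out = mecr(counts, [("g1", "g2")])
        assert out[("g1", "g2")] == pytest.approx(1 / 3)

    def test_undefined_when_never_expressed(self):
        counts = _counts([[0, 0]], ["g1", "g2"])
        assert np.isnan(mecr(counts, [("g1", "g2")])[("g1", "g2")])

    def test_full_coexpression_is_one(self):
        counts = _counts([[1, 1], [2, 2]], ["g1", "g2"])
        assert mecr(counts, [("g1", "g2")])[("g1", "g2")] == 1.0

    def test_invariant_to_cells_expressing_neither(self):
        base = _counts([[2, 0], [0, 1], [3, 4]], ["g1", "g2"])
        padded = pd.concat([base, _counts([[0, 0]] * 5, ["g1", "g2"])])
        pair = ("g1", "g2")
        assert mecr(base, [pair])[pair] == mecr(padded, [pair])[pair]

    def test_unmeasured_gene_rejected(self):
        counts = _counts([[1, 0]], ["g1", "g2"])
        with pytest.raises(ValueError):
            mecr(counts, [("g1", "gX")])


def _result_from_assignments(assignments, sources=None):
    tids = list(assignments)
    sources = sources or [
        "model" if assignments[t] != UNASSIGNED else "none" for t in tids
    ]
    rows = pd.DataFrame(
        {
            "transcript_id": tids,
            "assignment": [assignments[t] for t in tids],
            "score": [0.9 if s == "model" else np.nan for s in sources],
            "source": sources,
        }
    )
    return SegmentationResult(rows=rows)


def _transcripts_for(result, gene="g1"):
    return pd.DataFrame(
        {
            "transcript_id": result.rows["transcript_id"],
            "gene": gene,
            "x": 0.0, "y": 0.0, "z": 0.0, "quality": 40.0, "prior_cell_id": pd.NA,
        }
    )


class TestSummaryStats:
    def test_median_counts(self):
        assignments = {}
        for cell, n in [("a", 10), ("b", 20), ("c", 30)]:
            for i in range(n):
                assignments[f"{cell}{i:03d}"] = cell
        res = _result_from_assignments(assignments)
        rep = summary_stats(res, _transcripts_for(res), min_counts=5)
        assert rep.n_cells == 3 and rep.median_counts_per_cell == 20

    def test_min_counts_excludes_cell(self):
        assignments = {f"a{i}": "a" for i in range(10)}
        assignments.update({f"b{i}": "b" for i in range(3)})
        res = _result_from_assignments(assignments)
        rep = summary_stats(res, _transcripts_for(res), min_counts=5)
        assert rep.n_cells == 1

    def test_area_absent_without_polygons(self):
        res = _result_from_assignments({f"t{i}": "a" for i in range(6)})
        rep = summary_stats(res, _transcripts_for(res))
        assert rep.median_area is None


class TestAssignmentPRF:
    def test_perfect_assignment(self):
        truth = pd.Series({f"t{i}": f"c{i % 2}" for i in range(10)})
        res = _result_from_assignments({t: truth[t] for t in truth.index})
        assert assignment_prf(res, truth) == (1.0, 1.0, 1.0)

    def test_everything_unassigned_reports_zero(self):
        truth = pd.Series({f"t{i}": "c0" for i in range(4)})
        res = _result_from_assignments({t: UNASSIGNED for t in truth.index})
        assert assignment_prf(res, truth) == (0.0, 0.0, 0.0)

    def test_two_by_two_confusion_hand_computed(self):
        # true cells A (4 transcripts) and B (4); prediction swaps half of B into A's object
        truth = pd.Series(
            {**{f"a{i}": "A" for i in range(4)}, **{f"b{i}": "B" for i in range(4)}}
        )
        pred = {f"a{i}": "pA" for i in range(4)}
        pred.update({"b0": "pA", "b1": "pA", "b2": "pB", "b3": "pB"})
        res = _result_from_assignments(pred)
        p, r, f1 = assignment_prf(res, truth)
        # overlap: pA x A = 4, pA x B = 2, pB x B = 2 -> match pA-A, pB-B, TP = 6
        assert p == pytest.approx(6 / 8)
        assert r == pytest.approx(6 / 8)

    @staticmethod
    def _exhaustive_best(overlap):
        # pad to square and enumerate one-sided permutations of a square
        # cost matrix: equivalent to trying every full matching
        m = overlap.to_numpy()
        n = max(m.shape)
        sq = np.zeros((n, n), dtype=m.dtype)
        sq[: m.shape[0], : m.shape[1]] = m
        rows = np.arange(n)
        return max(sq[rows, list(perm)].sum() for perm in itertools.permutations(range(n)))

    @pytest.mark.parametrize("seed", range(4))
    def test_greedy_within_half_of_exhaustive_optimum(self, seed):
        # greedy largest-overlap matching carries the classical 1/2 guarantee
        rng = np.random.default_rng(seed)
        n_pred, n_true = rng.integers(2, 5), rng.integers(2, 5)
        overlap = pd.DataFrame(
            rng.integers(0, 6, size=(n_pred, n_true)),
            index=[f"p{i}" for i in range(n_pred)],
            columns=[f"T{j}" for j in range(n_true)],
        )
        matching = greedy_match(overlap)
        greedy_total = sum(overlap.loc[p, t] for p, t in matching.items())
        best = self._exhaustive_best(overlap)
        assert greedy_total <= best
        assert 2 * greedy_total >= best

    def test_greedy_exact_when_objects_dominantly_overlap_one_cell(self):
        # the regime segmentation overlap tables are in: each predicted cell
        # shares most transcripts with a single true cell
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(2, 7))
            noise = rng.integers(0, 3, size=(n, n))
            np.fill_diagonal(noise, 0)
            overlap = pd.DataFrame(
                np.diag(rng.integers(20, 40, size=n)) + noise,
                index=[f"p{i}" for i in range(n)],
                columns=[f"T{j}" for j in range(n)],
            )
            matching = greedy_match(overlap)
            greedy_total = sum(overlap.loc[p, t] for p, t in matching.items())
            assert greedy_total == self._exhaustive_best(overlap)
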