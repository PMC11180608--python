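"""Evaluation metrics: exact counts, null calibrations, invariances."""

import numpy as np
import pytest

from alnvec.diffdp import AlignmentPath
from alnvec.metrics import (
    alignment_prf,
    cluster_adjusted_mi,
    retrieval_sensitivity,
    triplet_auprc,
)
from alnvec.synthetic import generate_labeled_vectors
from alnvec.vector_index import SearchHit


def _hit(q, h, rank, tm=0.9):
    return SearchHit(query_id=q, hit_id=h, predicted_tm=tm, rank=rank)


class TestAlignmentPRF:
    def test_identical_paths_are_perfect(self):
        p = AlignmentPath("MMXYM")
        assert alignment_prf(p, p) == (1.0, 1.0, 1.0)

    def test_disjoint_edge_sets_are_zero(self):
        pred = AlignmentPath("MXY")  # edge (1,1)
        truth = AlignmentPath("XYM")  # edge (2,2)
        assert alignment_prf(pred, truth) == (0.0, 0.0, 0.0)

    def test_half_overlap_counts(self):
        pred = AlignmentPath.from_edges([(1, 1), (2, 2), (3, 3), (4, 4)], 5, 5)
        truth = AlignmentPath.from_edges([(1, 1), (2, 2), (4, 5), (5, 4)][:2] + [(3, 4), (4, 5)], 5, 5)
        prec, rec, f1 = alignment_prf(pred, truth)
        assert (prec, rec, f1) == (0.5, 0.5, 0.5)

    def test_swapping_arguments_swaps_precision_and_recall(self):
        pred = AlignmentPath.from_edges([(1, 1), (2, 2), (3, 3)], 4, 4)
        truth = AlignmentPath.from_edges([(1, 1), (2, 2)], 4, 4)
        p1, r1, f1a = alignment_prf(pred, truth)
        p2, r2, f1b = alignment_prf(truth, pred)
        assert (p1, r1) == (r2, p2)
        assert f1a == pytest.approx(f1b)

    def test_empty_prediction_has_zero_precision(self):
        pred = AlignmentPath("XXYY")  # no matches
        truth = AlignmentPath("MM")
        assert alignment_prf(pred, truth) == (0.0, 0.0, 0.0)

    def test_mismatched_spans_rejected(self):
        with pytest.raises(ValueError):
            alignment_prf(AlignmentPath("MM"), AlignmentPath("MMM"))


class TestRetrievalSensitivity:
    ANN = {"q1": "famA", "q2": "famB", "q3": "famC", "q4": "famD",
           "h1": "famA", "h2": "famB", "h3": "famX", "h4": "famD"}

    def test_rank_one_hits_sharing_labels_give_100_percent(self):
        hits = {q: [_hit(q, f"h{q[1]}", 1)] for q in ("q1", "q2", "q4")}
        assert retrieval_sensitivity(hits, self.ANN, 1) == 100.0

    def test_three_of_four_queries_succeed(self):
        hits = {
            "q1": [_hit("q1", "h1", 1), _hit("q1", "h3", 2)],
            "q2": [_hit("q2", "h3", 1), _hit("q2", "h2", 2)],
            "q3": [_hit("q3", "h1", 1), _hit("q3", "h2", 2)],
            "q4": [_hit("q4", "h4", 1), _hit("q4", "h3", 2)],
        }
        assert retrieval_sensitivity(hits, self.ANN, 2) == 75.0
        # at n=1 only q1 and q4 succeed
        assert retrieval_sensitivity(hits, self.ANN, 1) == 50.0

    def test_n_exceeding_hit_list_rejected(self):
        hits = {"q1": [_hit("q1", "h1", 1)]}
        with pytest.raises(ValueError, match="exceeds"):
            retrieval_sensitivity(hits, self.ANN, 5)

    def test_unannotated_id_named_in_error(self):
        hits = {"q1": [_hit("q1", "mystery", 1)]}
        with pytest.raises(KeyError, match="mystery"):
            retrieval_sensitivity(hits, self.ANN, 1)


class TestTripletAUPR:
    def test_perfectly_separated_labels_give_one(self):
        vectors, labels = generate_labeled_vectors(
            n_classes=3, per_class=10, dim=8, separation=50.0, seed=0
        )
        assert triplet_auprc(vectors, labels, n_triplets=500, seed=1) == pytest.approx(1.0)

    def test_labels_independent_of_vectors_score_at_chance(self):
        rng = np.random.default_rng(0)
        vectors = rng.normal(0, 1, (200, 16))
        labels = [f"c{i % 5}" for i in range(200)]  # independent of the vectors
        aupr = triplet_auprc(vectors, labels, n_triplets=2000, seed=2)
        assert aupr == pytest.approx(0.5, abs=0.05)

    def test_duplicate_vector_pair_scores_cosine_one(self):
        v = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, -1.0], [4.0, 0.0]])
        labels = ["dup", "dup", "other", "other"]
        # the only same-label pair for 'dup' is the duplicate: AUPR must be 1
        assert triplet_auprc(v, labels, n_triplets=200, seed=0) == pytest.approx(1.0)

    def test_impossible_sampling_rejected(self):
        with pytest.raises(ValueError, match="sampling"):
            triplet_auprc(np.eye(3), ["a", "b", "c"], n_triplets=10, seed=0)


class TestClusterAMI:
    def test_well_separated_blobs_recover_labels(self):
        vectors, labels = generate_labeled_vectors(
            n_classes=5, per_class=30, dim=16, separation=8.0, seed=3
        )
        assert cluster_adjusted_mi(vectors, labels, n_clusters=5, seed=0) >= 0.95

    def test_shuffled_labels_score_near_zero(self):
        rng = np.random.default_rng(1)
        vectors, labels = generate_labeled_vectors(
            n_classes=5, per_class=100, dim=16, separation=8.0, seed=3
        )
        shuffled = list(labels)
        rng.shuffle(shuffled)
        assert abs(cluster_adjusted_mi(vectors, shuffled, n_clusters=5, seed=0)) <= 0.05

    def test_invariant_to_label_renaming(self):
        vectors, labels = generate_labeled_vectors(
            n_classes=4, per_class=20, dim=8, separation=6.0, seed=5
        )
        renamed = [f"renamed-{lab}" for lab in labels]
        a = cluster_adjusted_mi(vectors, labels, n_clusters=4, seed=0)
        b = cluster_adjusted_mi(vectors, renamed, n_clusters=4, seed=0)
        assert a == pytest.approx(b)

    def test_identical_vectors_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cluster_adjusted_mi(np.ones((10, 4)), ["a"] * 5 + ["b"] * 5, n_clusters=2)

    def test_separation_increases_ami(self):
        scores = []
        for sep in (0.5, 3.0, 8.0):
            vectors, labels = generate_labeled_vectors(
                n_classes=3, per_class=25, dim=8, separation=sep, seed=7
            )
            scores.append(cluster_adjusted_mi(vectors, labels, n_clusters=3, seed=0))
        assert scores[0] < scores[1] < scores[2]
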