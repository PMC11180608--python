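"""Evaluation statistics for alignments, retrieval and embeddings.

* alignment precision/recall -- an alignment is a bipartite graph whose
  edges are matched residue pairs; precision and recall compare the edge
  sets of a predicted and a reference alignment.
* retrieval sensitivity -- the percentage of queries whose annotation
  appears among the annotations of their top-n returned neighbors.
* triplet-scoring AUPR -- sample triplets with two members sharing a label
  and one drawn from another label; same-label pairs are positives,
  an equal number of cross-label pairs negatives, cosine similarity is the
  classifier score, and the area under the precision-recall curve (step-wise
  interpolation, no linear segments) summarizes separability.
* cluster-adjusted mutual information -- spectral clustering on a cosine
  affinity (shifted to be nonnegative), scored by adjusted mutual
  information against the true labels.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.cluster import SpectralClustering
from sklearn.metrics import adjusted_mutual_info_score, average_precision_score

from .diffdp import AlignmentPath
from .vector_index import SearchHit

__all__ = [
    "alignment_prf",
    "retrieval_sensitivity",
    "triplet_auprc",
    "cluster_adjusted_mi",
]


def alignment_prf(predicted: AlignmentPath, truth: AlignmentPath) -> tuple[float, float, float]:
    """Edge precision, recall and F1 of a predicted vs reference alignment.

    An empty predicted edge set has precision 0 by convention (and hence
    F1 = 0).  Swapping the arguments swaps precision and recall."""
    if (predicted.p, predicted.q) != (truth.p, truth.q):
        raise ValueError(
            f"paths span different sequences: {(predicted.p, predicted.q)} vs {(truth.p, truth.q)}"
        )
    inter = len(predicted.edges & truth.edges)
    precision = inter / len(predicted.edges) if predicted.edges else 0.0
    recall = inter / len(truth.edges) if truth.edges else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1


def retrieval_sensitivity(
    hits: Mapping[str, Sequence[SearchHit]] | Iterable[Sequence[SearchHit]],
    annotations: Mapping[str, set[str] | str],
    n: int,
) -> float:
    """Percentage of queries whose label set intersects its top-n hits' labels."""
    if not isinstance(hits, Mapping):
        hits = {hl[0].query_id: hl for hl in hits if hl}
    if not hits:
        raise ValueError("no hit lists supplied")

    def labels_of(sid: str) -> set[str]:
        if sid not in annotations:
            raise KeyError(f"id {sid!r} has no annotation")
        lab = annotations[sid]
        return {lab} if isinstance(lab, str) else set(lab)

    successes = 0
    for qid, hit_list in hits.items():
        if n > len(hit_list):
            raise ValueError(f"n={n} exceeds hit list length {len(hit_list)} for query {qid!r}")
        top = sorted(hit_list, key=lambda h: h.rank)[:n]
        hit_labels: set[str] = set()
        for h in top:
            hit_labels |= labels_of(h.hit_id)
        if labels_of(qid) & hit_labels:
            successes += 1
    return 100.0 * successes / len(hits)


def _cosine_matrix(vectors: np.ndarray) -> np.ndarray:
    v = np.asarray(vectors, dtype=np.float64)
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("zero-norm vector")
    vn = v / norms
    return vn @ vn.T


def triplet_auprc(
    vectors: np.ndarray,
    labels: Sequence[str],
    n_triplets: int = 2000,
    seed: int = 0,
) -> float:
    """Triplet-scoring AUPR of labeled embeddings.

    Each triplet draws a label with >= 2 members, two distinct members of it
    (the positive pair) and one member of a different label (anchor vs
    negative pair).  Cosine similarity scores the balanced positive/negative
    pair set; the average-precision summary uses step-wise interpolation.
    Sampling is with replacement across triplets and seeded."""
    labels = list(labels)
    v = np.asarray(vectors, dtype=np.float64)
    if len(labels) != v.shape[0]:
        raise ValueError("one label per vector required")
    by_label: dict[str, list[int]] = defaultdict(list)
    for i, lab in enumerate(labels):
        by_label[lab].append(i)
    eligible = sorted(lab for lab, idx in by_label.items() if len(idx) >= 2)
    others = {lab: sorted(set(range(len(labels))) - set(by_label[lab])) for lab in eligible}
    eligible = [lab for lab in eligible if others[lab]]
    if not eligible:
        raise ValueError("triplet sampling impossible: no label with >= 2 members and an outgroup")
    rng = np.random.default_rng(seed)
    cos = _cosine_matrix(v)
    scores, truth = [], []
    for _ in range(n_triplets):
        lab = eligible[rng.integers(len(eligible))]
        a, b = rng.choice(by_label[lab], size=2, replace=False)
        c = others[lab][rng.integers(len(others[lab]))]
        scores.append(cos[a, b])
        truth.append(1)
        scores.append(cos[a, c])
        truth.append(0)
    return float(average_precision_score(truth, scores))


def cluster_adjusted_mi(
    vectors: np.ndarray,
    labels: Sequence[str],
    n_clusters: int = 5,
    seed: int = 0,
) -> float:
    """Adjusted mutual information of spectral clustering vs true labels.

    Clustering runs on a precomputed cosine affinity shifted to [0, 1]
    ((1 + cos)/2).  AMI is invariant to label renaming and is ~0 for
    label assignments independent of the vectors."""
    v = np.asarray(vectors, dtype=np.float64)
    labels = list(labels)
    if len(labels) != v.shape[0]:
        raise ValueError("one label per vector required")
    if v.shape[0] < n_clusters:
        raise ValueError("need at least n_clusters vectors")
    cos = _cosine_matrix(v)
    if np.allclose(cos, 1.0):
        raise ValueError("degenerate affinity: all vectors identical")
    affinity = (1.0 + cos) / 2.0
    sc = SpectralClustering(
        n_clusters=n_clusters, affinity="precomputed", random_state=seed
    )
    assign = sc.fit_predict(affinity)
    return float(adjusted_mutual_info_score(labels, assign))
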