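"""Seeded synthetic corpora: homolog pairs, planted alignments, labels, blobs.

Real training data for this kind of model come from structural databases:
millions of sequence pairs labeled with TM-scores from structure comparison,
plus the residue-level alignments those comparisons imply.  This module
plants the same signal synthetically so every component is testable offline:

* families evolve from a random ancestor by per-site substitutions and
  geometric-length indels, each member at its own divergence;
* the mutation/indel history implies an exact ground-truth alignment
  between any two members (composed through shared ancestor positions);
* a pair's similarity label decays with total divergence,
  label = exp(-lambda * divergence) + Gaussian noise, clamped to [0, 1] --
  a stand-in for TM-scores that is monotone and bounded, which is all
  parameter-recovery experiments need (lambda = 2, sigma = 0.02 default);
* cross-family ("unrelated") pairs draw labels from a low-similarity
  distribution with mean below 0.2, matching the convention that scores
  under 0.2 mean unrelated proteins;
* labeled Gaussian blobs stand in for fold-labeled embedding corpora.

Everything is a pure function of (config, seed): identical inputs give
bit-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

from .aligner import AlignmentRecord, GroundTruthAlignment
from .diffdp import AlignmentPath
from .embedder import ALPHABET
from .tmvec_encoder import PairRecord

__all__ = [
    "GeneratorConfig",
    "PairCorpus",
    "mutate_sequence",
    "compose_alignment",
    "generate_pair_corpus",
    "generate_labeled_vectors",
    "planted_label",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Divergence is the per-site substitution probability of one member
    relative to its family ancestor; a pair's divergence is the sum over its
    two branches.  Indels fire per site at ``indel_rate * divergence`` and
    have geometric lengths with success probability ``indel_length_p``
    (mean length 2 at the 0.5 default).
    """

    seed: int = 0
    n_families: int = 12
    members_per_family: int = 4
    ancestor_length_range: tuple[int, int] = (100, 200)
    max_divergence: float = 0.35
    substitution_rate: float = 1.0  # substitution prob per unit divergence
    indel_rate: float = 0.1  # indel prob per site per unit divergence
    indel_length_p: float = 0.5
    lambda_decay: float = 2.0
    noise_sigma: float = 0.02
    unrelated_fraction: float = 0.2

    def __post_init__(self):
        if not (0.0 <= self.substitution_rate <= 1.0 and 0.0 <= self.indel_rate < 1.0):
            raise ValueError("rates must lie in [0, 1) (an indel rate of 1 is infeasible)")
        if not (0.0 < self.indel_length_p <= 1.0):
            raise ValueError("indel_length_p must be in (0, 1]")
        if not (0.0 <= self.unrelated_fraction < 1.0):
            raise ValueError("unrelated_fraction must be in [0, 1)")
        if self.ancestor_length_range[0] < 2 or self.ancestor_length_range[0] > self.ancestor_length_range[1]:
            raise ValueError("invalid ancestor length range")
        if not (0.0 <= self.max_divergence <= 0.95):
            raise ValueError("max_divergence must be in [0, 0.95]")


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def mutate_sequence(
    ancestor: str, divergence: float, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Evolve one member from the ancestor at the given divergence.

    Returns (sequence, anc_map) where anc_map[k] is the 0-based member
    position carrying ancestor position k, or -1 if that site was deleted.
    Substitutions replace a residue uniformly over the 20-letter alphabet
    (so a fraction 1/20 of draws are silent); insertions and deletions fire
    with equal probability and geometric lengths."""
    p_sub = min(config.substitution_rate * divergence, 0.95)
    p_indel = min(config.indel_rate * divergence, 0.5)
    letters = list(ALPHABET)
    out: list[str] = []
    anc_map = np.full(len(ancestor), -1, dtype=np.int64)
    k = 0
    n = len(ancestor)
    while k < n:
        r = rng.random()
        if r < p_indel / 2.0:  # insertion before this site
            for _ in range(rng.geometric(config.indel_length_p)):
                out.append(letters[rng.integers(20)])
        elif r < p_indel:  # deletion run starting at this site
            k += int(rng.geometric(config.indel_length_p))
            continue
        anc_map[k] = len(out)
        ch = ancestor[k]
        if rng.random() < p_sub:
            ch = letters[rng.integers(20)]
        out.append(ch)
        k += 1
    if not out:  # degenerate: everything deleted; keep one residue
        out.append(letters[rng.integers(20)])
    return "".join(out), anc_map


def compose_alignment(
    map_a: np.ndarray, map_b: np.ndarray, len_a: int, len_b: int
) -> AlignmentPath:
    """Ground-truth alignment of two members through shared ancestor sites."""
    edges = [
        (int(a) + 1, int(b) + 1)
        for a, b in zip(map_a, map_b)
        if a >= 0 and b >= 0
    ]
    return AlignmentPath.from_edges(edges, len_a, len_b)


def planted_label(divergence: float, config: GeneratorConfig, rng: np.random.Generator) -> float:
    noisy = float(np.exp(-config.lambda_decay * divergence) + rng.normal(0.0, config.noise_sigma))
    return min(1.0, max(0.0, noisy))


@dataclass
class PairCorpus:
    """Everything one synthetic study emits."""

    sequences: dict[str, str]
    pairs: list[PairRecord]
    alignments: dict[tuple[str, str], GroundTruthAlignment]
    divergences: dict[tuple[str, str], float]
    families: dict[str, str]  # sequence id -> family annotation
    config: GeneratorConfig = field(repr=False, default=None)

    def alignment_records(self) -> list[AlignmentRecord]:
        out = []
        for (ida, idb), truth in self.alignments.items():
            out.append(
                AlignmentRecord(id_a=ida, id_b=idb, truth=truth, tm_label=truth.source_label)
            )
        return out


def generate_pair_corpus(config: GeneratorConfig = GeneratorConfig()) -> PairCorpus:
    """Simulate families, pairs, planted alignments and similarity labels.

    Member 0 of each family is the ancestor itself (divergence 0); the rest
    sit at divergences drawn uniformly from (0, max_divergence].  Related
    pairs are all within-family member pairs; unrelated cross-family pairs
    are added so they make up ``unrelated_fraction`` of the pair table.
    """
    rng = np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    families: dict[str, str] = {}
    member_div: dict[str, float] = {}
    member_map: dict[str, np.ndarray] = {}
    fam_members: list[list[str]] = []

    lo, hi = config.ancestor_length_range
    for f in range(config.n_families):
        fam = f"fam{f:03d}"
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_sequence(length, rng)
        members = []
        for m in range(config.members_per_family):
            sid = f"{fam}_m{m}"
            div = 0.0 if m == 0 else float(rng.uniform(0.0, config.max_divergence))
            seq, amap = mutate_sequence(ancestor, div, config, rng)
            sequences[sid] = seq
            families[sid] = fam
            member_div[sid] = div
            member_map[sid] = amap
            members.append(sid)
        fam_members.append(members)

    pairs: list[PairRecord] = []
    alignments: dict[tuple[str, str], GroundTruthAlignment] = {}
    divergences: dict[tuple[str, str], float] = {}

    for members in fam_members:
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ida, idb = members[i], members[j]
                div = member_div[ida] + member_div[idb]
                label = planted_label(div, config, rng)
                path = compose_alignment(
                    member_map[ida], member_map[idb], len(sequences[ida]), len(sequences[idb])
                )
                truth = GroundTruthAlignment.from_states(path.states, source_label=label)
                pairs.append(PairRecord(id_a=ida, id_b=idb, label=label))
                alignments[(ida, idb)] = truth
                divergences[(ida, idb)] = div

    n_related = len(pairs)
    n_unrelated = int(round(config.unrelated_fraction / (1.0 - config.unrelated_fraction) * n_related))
    all_ids = sorted(sequences)
    fam_of = families
    attempts = 0
    while n_unrelated > 0 and attempts < 50 * n_unrelated and config.n_families > 1:
        ida, idb = (all_ids[k] for k in rng.integers(0, len(all_ids), size=2))
        attempts += 1
        if fam_of[ida] == fam_of[idb] or (ida, idb) in divergences or ida == idb:
            continue
        # low-similarity label: unrelated structures score below 0.2
        label = float(rng.uniform(0.02, 0.2))
        pairs.append(PairRecord(id_a=ida, id_b=idb, label=label))
        divergences[(ida, idb)] = float("nan")
        n_unrelated -= 1

    return PairCorpus(
        sequences=sequences,
        pairs=pairs,
        alignments=alignments,
        divergences=divergences,
        families=families,
        config=config,
    )


def generate_labeled_vectors(
    n_classes: int = 5,
    per_class: int = 40,
    dim: int = 16,
    separation: float = 4.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Gaussian blobs with controllable separation, as labeled embeddings.

    ``separation`` scales the distance between unit-variance class centers;
    0 makes all classes identical in distribution (chance-level structure).
    """
    if n_classes < 1 or per_class < 1:
        raise ValueError("n_classes and per_class must be positive")
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, 1.0, size=(n_classes, dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= separation
    vectors = np.vstack(
        [centers[c] + rng.normal(0.0, 1.0, size=(per_class, dim)) for c in range(n_classes)]
    )
    labels = [f"class{c}" for c in range(n_classes) for _ in range(per_class)]
    return vectors, labels
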