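"""Trainable sequence-to-alignment model (embedder + scoring heads + smoothed NW).

A pair of sequences is embedded, scored by the convolutional match/gap heads,
and pushed through the smoothed Needleman-Wunsch layer; the expected
alignment e (a matrix of per-cell match probabilities) is compared with the
ground-truth alignment e* by the cross-entropy

    L(e*, e) = - (1/pq) sum_ij [ e*_ij log e_ij + (1 - e*_ij) log(1 - e_ij) ]

(the per-cell mean of the binomial log-likelihood; a ``sum`` reduction is
available).  Gradients reach the head parameters through the exact
Hessian-vector-product pullback of the NW layer, so the whole model trains
end-to-end with Adam (reference initial learning rate 5e-4).

Training data are filtered the way structural-alignment training sets are:
records whose alignment contains a run of more than 10 consecutive gap
states, or whose structural-similarity label is below 0.6, are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import nn
from .diffdp import (
    AlignmentPath,
    ExpectedAlignment,
    PROB_FLOOR,
    ScoreMatrices,
    SmoothingConfig,
    _adjoint,
    _directional_kernel,
    nw_forward,
    nw_hard_decode,
)
from .embedder import ResidueEmbeddings, ToyEmbedder, embed_residues
from .scoring_heads import ScoringHeadConfig, ScoringHeads
from .tmvec_encoder import TrainingLog

__all__ = [
    "GroundTruthAlignment",
    "AlignmentRecord",
    "AlignmentResult",
    "DeepBLASTModel",
    "alignment_loss",
    "align_pair",
    "filter_training_alignments",
    "max_gap_run",
    "train_deepblast",
    "render_alignment_text",
]

# consecutive-gap exclusion threshold: runs of MORE than this many gap states
# (i.e. >= MAX_GAP_RUN + 1) are dropped; runs of exactly MAX_GAP_RUN are kept
MAX_GAP_RUN = 10
# structural-similarity exclusion threshold: labels strictly below are dropped
MIN_TM_LABEL = 0.6


@dataclass(frozen=True)
class GroundTruthAlignment:
    """Binary ground-truth match matrix e* (p x q).

    At most one 1 per row and per column, jointly strictly increasing (a
    monotone matching).  ``states`` optionally preserves the gap ordering of
    the generating alignment; ``source_label`` its structural similarity.
    """

    estar: np.ndarray
    source_label: float | None = None
    states: str | None = None

    def __post_init__(self):
        m = np.ascontiguousarray(np.asarray(self.estar, dtype=np.float64))
        object.__setattr__(self, "estar", m)
        if m.ndim != 2:
            raise ValueError("e* must be 2-D")
        if not np.isin(m, (0.0, 1.0)).all():
            raise ValueError("e* entries must be 0 or 1")
        if (m.sum(axis=0) > 1).any() or (m.sum(axis=1) > 1).any():
            raise ValueError("e* must have at most one match per row and column")
        ii, jj = np.nonzero(m)
        order = np.argsort(ii)
        if not (np.diff(jj[order]) > 0).all():
            raise ValueError("matches must be strictly increasing in both coordinates")

    @classmethod
    def from_states(
        cls, states: str, source_label: float | None = None
    ) -> "GroundTruthAlignment":
        path = AlignmentPath(states)
        m = np.zeros((path.p, path.q))
        for i, j in path.edges:
            m[i - 1, j - 1] = 1.0
        return cls(estar=m, source_label=source_label, states=states)

    def to_path(self) -> AlignmentPath:
        if self.states is not None:
            return AlignmentPath(self.states)
        p, q = self.estar.shape
        edges = [(i + 1, j + 1) for i, j in zip(*np.nonzero(self.estar))]
        return AlignmentPath.from_edges(edges, p, q)

    @property
    def shape(self) -> tuple[int, int]:
        return self.estar.shape


@dataclass(frozen=True)
class AlignmentRecord:
    """One training example: a sequence pair, its alignment and its label."""

    id_a: str
    id_b: str
    truth: GroundTruthAlignment
    tm_label: float

    def __post_init__(self):
        if not (0.0 <= self.tm_label <= 1.0):
            raise ValueError(f"tm_label outside [0,1] for ({self.id_a}, {self.id_b})")


def alignment_loss(estar, e, reduction: str = "mean") -> float:
    """Cross-entropy between ground truth e* and expected alignment e.

    Accepts a GroundTruthAlignment or a raw 0/1 matrix, and an
    ExpectedAlignment or raw probability matrix.  Probabilities are clamped
    to [PROB_FLOOR, 1 - PROB_FLOOR] before the logs."""
    t = estar.estar if isinstance(estar, GroundTruthAlignment) else np.asarray(estar, float)
    pr = e.e if isinstance(e, ExpectedAlignment) else np.asarray(e, float)
    if t.shape != pr.shape:
        raise ValueError(f"shape mismatch {t.shape} vs {pr.shape}")
    pr = np.clip(pr, PROB_FLOOR, 1.0 - PROB_FLOOR)
    ll = t * np.log(pr) + (1.0 - t) * np.log(1.0 - pr)
    return float(-ll.mean() if reduction == "mean" else -ll.sum())


def max_gap_run(states: str) -> int:
    """Longest run of consecutive identical gap states (X or Y).

    A run mixing X and Y counts as two separate runs."""
    best = run = 0
    prev = ""
    for c in states:
        if c in "XY" and c == prev:
            run += 1
        elif c in "XY":
            run = 1
        else:
            run = 0
        prev = c
        best = max(best, run)
    return best


def filter_training_alignments(
    records: Iterable[AlignmentRecord],
) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Drop records with a gap run longer than 10 or a label below 0.6.

    Boundary semantics: a run of exactly 10 gap states and a label of
    exactly 0.6 are both retained.  Returns (kept, report) where the report
    counts exclusions per reason."""
    kept: list[AlignmentRecord] = []
    report = {"kept": 0, "long_gap_run": 0, "low_tm": 0}
    for rec in records:
        try:
            states = rec.truth.states or rec.truth.to_path().states
        except Exception as exc:  # noqa: BLE001 - re-raise with the record name
            raise ValueError(f"malformed alignment for ({rec.id_a}, {rec.id_b}): {exc}") from exc
        if rec.tm_label < MIN_TM_LABEL:
            report["low_tm"] += 1
        elif max_gap_run(states) > MAX_GAP_RUN:
            report["long_gap_run"] += 1
        else:
            kept.append(rec)
            report["kept"] += 1
    return kept, report


# ---------------------------------------------------------------------------
# the NW layer as an autograd node
# ---------------------------------------------------------------------------


def expected_alignment_tensor(
    mu: nn.Tensor, gap: nn.Tensor, config: SmoothingConfig
) -> nn.Tensor:
    """Differentiable expected alignment of (mu, gap) score tensors.

    Forward runs the smoothed NW sweep; backward pulls the adjoint dL/de
    back to the scores with the exact directional-derivative sweep (see
    diffdp.nw_alignment_grads for the derivation)."""
    if not config.mu_on_gaps:
        raise NotImplementedError("trainable layer uses the mu-on-all-branches recursion")
    sm = ScoreMatrices(mu.data, gap.data)
    fwd = nw_forward(sm, config)
    E = _adjoint(fwd)
    e = np.ascontiguousarray(E[1:-1, 1:-1])
    out = nn.Tensor(e, (mu, gap))

    def bw(g):
        de = np.ascontiguousarray(np.asarray(g, dtype=np.float64))
        zeros = np.zeros_like(de)
        _, wdot, Ed = _directional_kernel(
            de, zeros, fwd.weights, E, config.temperature, True
        )
        edot = Ed[1:-1, 1:-1]
        if mu.requires_grad:
            mu._accum(edot)
        if gap.requires_grad:
            wx_wy = fwd.weights[:, :, 1] + fwd.weights[:, :, 2]
            gap._accum(edot * wx_wy + e * (wdot[:, :, 1] + wdot[:, :, 2]))

    out._backward = bw
    return out


def _loss_tensor(estar: np.ndarray, e: nn.Tensor, reduction: str = "mean") -> nn.Tensor:
    ec = nn.clamp(e, PROB_FLOOR, 1.0 - PROB_FLOOR)
    t = nn.constant(estar)
    ll = t * ec.log() + (1.0 - t) * (1.0 - ec).log()
    return -(ll.mean() if reduction == "mean" else ll.sum())


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class AlignmentResult:
    expected: ExpectedAlignment
    path: AlignmentPath
    score: float
    text: str
    gapped_fasta: str
    low_confidence: bool


class DeepBLASTModel:
    """Embedder + scoring heads + smoothed NW, bundled for alignment."""

    def __init__(
        self,
        heads: ScoringHeads | None = None,
        embedder=None,
        config: SmoothingConfig = SmoothingConfig(),
        low_confidence_threshold: float = 0.5,
    ):
        self.heads = heads if heads is not None else ScoringHeads()
        self.embedder = embedder if embedder is not None else ToyEmbedder(
            d=self.heads.config.d, seed=0
        )
        self.config = config
        self.low_confidence_threshold = low_confidence_threshold

    def embed(self, seq: str, sid: str = "") -> ResidueEmbeddings:
        return embed_residues(seq, backend=self.embedder, sequence_id=sid)

    def scores(self, ha: ResidueEmbeddings, hb: ResidueEmbeddings) -> ScoreMatrices:
        mu, gap = self.heads.score_tensors(ha.vectors, hb.vectors)
        return ScoreMatrices(mu=mu.data, gap=gap.data)


def align_pair(
    seq_a: str, seq_b: str, model: DeepBLASTModel, id_a: str = "query", id_b: str = "target"
) -> AlignmentResult:
    """Align two sequences: expected alignment, hard decoded path, rendered text.

    The returned path comes from the classical (hard) decode on the learned
    scores, which guarantees a valid monotone alignment; thresholding the
    expected-alignment marginals is available separately via the e matrix.
    A low-confidence flag is set when no cell of e reaches the threshold."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    ha, hb = model.embed(seq_a, id_a), model.embed(seq_b, id_b)
    sm = model.scores(ha, hb)
    fwd = nw_forward(sm, model.config)
    E = _adjoint(fwd)
    expected = ExpectedAlignment(e=np.ascontiguousarray(E[1:-1, 1:-1]), config=model.config)
    score, path = nw_hard_decode(sm, mu_on_gaps=model.config.mu_on_gaps)
    low_conf = bool(expected.e.max() < model.low_confidence_threshold)
    text = render_alignment_text(seq_a, seq_b, path)
    fasta = _gapped_fasta(seq_a, seq_b, path, id_a, id_b)
    return AlignmentResult(
        expected=expected,
        path=path,
        score=score,
        text=text,
        gapped_fasta=fasta,
        low_confidence=low_conf,
    )


def _gapped_strings(seq_a: str, seq_b: str, path: AlignmentPath) -> tuple[str, str, str]:
    if (path.p, path.q) != (len(seq_a), len(seq_b)):
        raise ValueError("path does not span the sequences")
    ga, gb, mid = [], [], []
    i = j = 0
    for c in path.states:
        if c == "M":
            ga.append(seq_a[i])
            gb.append(seq_b[j])
            mid.append("|")
            i += 1
            j += 1
        elif c == "X":
            ga.append(seq_a[i])
            gb.append("-")
            mid.append(" ")
            i += 1
        else:
            ga.append("-")
            gb.append(seq_b[j])
            mid.append(" ")
            j += 1
    return "".join(ga), "".join(gb), "".join(mid)


def render_alignment_text(
    seq_a: str, seq_b: str, path: AlignmentPath, width: int = 60
) -> str:
    """Three-row pairwise alignment blocks: gapped query, match line, gapped target."""
    ga, gb, mid = _gapped_strings(seq_a, seq_b, path)
    blocks = []
    for start in range(0, len(ga), width):
        blocks.append(
            "\n".join((ga[start : start + width], mid[start : start + width], gb[start : start + width]))
        )
    return "\n\n".join(blocks)


def _gapped_fasta(seq_a: str, seq_b: str, path: AlignmentPath, id_a: str, id_b: str) -> str:
    ga, gb, _ = _gapped_strings(seq_a, seq_b, path)
    return f">{id_a}\n{ga}\n>{id_b}\n{gb}\n"


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _edge_prf(pred: AlignmentPath, truth: AlignmentPath) -> tuple[float, float]:
    inter = len(pred.edges & truth.edges)
    prec = inter / len(pred.edges) if pred.edges else 0.0
    rec = inter / len(truth.edges) if truth.edges else 0.0
    return prec, rec


def train_deepblast(
    records: list[AlignmentRecord],
    sequences: dict[str, str],
    heads_config: ScoringHeadConfig = ScoringHeadConfig(),
    embedder=None,
    config: SmoothingConfig = SmoothingConfig(),
    lr: float = 5e-4,
    batch_size: int = 16,
    epochs: int = 15,
    val_fraction: float = 0.15,
    patience: int = 3,
    seed: int = 0,
    apply_filter: bool = True,
    max_val_decode: int = 24,
) -> tuple[DeepBLASTModel, TrainingLog]:
    """Fit the scoring heads on ground-truth alignments (Adam, cross-entropy).

    Training stops early once the validation loss has not decreased for
    ``patience`` epochs; the best-validation snapshot is restored.  The log
    also records held-out median edge precision/recall per epoch (on up to
    ``max_val_decode`` decoded validation pairs).  Fully seeded."""
    if apply_filter:
        records, _ = filter_training_alignments(records)
    if not records:
        raise ValueError("no training alignments remain after filtering")
    rng = np.random.default_rng(seed)
    if embedder is None:
        embedder = ToyEmbedder(d=heads_config.d, seed=0)
    model = DeepBLASTModel(heads=ScoringHeads(heads_config), embedder=embedder, config=config)

    emb: dict[str, np.ndarray] = {}
    for rec in records:
        for sid in (rec.id_a, rec.id_b):
            if sid not in emb:
                if sid not in sequences:
                    raise KeyError(f"alignment references unknown sequence id {sid!r}")
                emb[sid] = model.embed(sequences[sid], sid).vectors

    order = rng.permutation(len(records))
    n_val = max(1, int(round(val_fraction * len(records)))) if len(records) > 1 else 0
    val = [records[i] for i in order[:n_val]]
    train = [records[i] for i in order[n_val:]] or list(records)

    opt = nn.Adam(model.heads.parameters(), lr=lr)
    log = TrainingLog()
    log.val_precision, log.val_recall = [], []  # type: ignore[attr-defined]
    best_state = nn.snapshot(model.heads)
    since_best = 0

    def _pair_loss(rec: AlignmentRecord) -> nn.Tensor:
        mu, gap = model.heads.score_tensors(emb[rec.id_a], emb[rec.id_b])
        e = expected_alignment_tensor(mu, gap, config)
        return _loss_tensor(rec.truth.estar, e)

    for epoch in range(epochs):
        idx = rng.permutation(len(train))
        total = 0.0
        for start in range(0, len(idx), batch_size):
            batch = [train[i] for i in idx[start : start + batch_size]]
            opt.zero_grad()
            loss = None
            for rec in batch:
                term = _pair_loss(rec)
                loss = term if loss is None else loss + term
            loss = loss * (1.0 / len(batch))
            loss.backward()
            opt.step()
            total += loss.item() * len(batch)
        log.train_loss.append(total / len(train))

        if val:
            vloss = float(np.mean([_pair_loss(r).item() for r in val]))
            precs, recs = [], []
            for rec in val[:max_val_decode]:
                sm = ScoreMatrices(*(t.data for t in model.heads.score_tensors(emb[rec.id_a], emb[rec.id_b])))
                _, pred = nw_hard_decode(sm, mu_on_gaps=config.mu_on_gaps)
                p_, r_ = _edge_prf(pred, rec.truth.to_path())
                precs.append(p_)
                recs.append(r_)
            log.val_loss.append(vloss)
            log.val_precision.append(float(np.median(precs)))  # type: ignore[attr-defined]
            log.val_recall.append(float(np.median(recs)))  # type: ignore[attr-defined]
            if vloss < log.best_val_loss - 1e-12:
                log.best_val_loss = vloss
                log.best_epoch = epoch
                best_state = nn.snapshot(model.heads)
                since_best = 0
            else:
                since_best += 1
                if since_best > patience:
                    break
    if val:
        model.heads.load_state_dict(best_state)
    return model, log
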