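"""Twin encoder phi: residue embeddings -> one structure-aware protein vector.

phi is a stack of transformer encoder layers followed by average pooling,
dropout and a small fully connected head.  It is trained as a twin (Siamese)
network: both proteins of a pair go through the *same* phi, and the cosine
similarity of the two output vectors is regressed onto the pair's structural
similarity label (a TM-score, in (0,1]) with an L1 objective

    loss = mean | cos(phi(a), phi(b)) - label |.

At query time the cosine similarity of two vectors *is* the predicted
TM-score, and the vectors themselves index a searchable database.

Reference-scale hyperparameters: d_in = 1024 residue embeddings, 4 attention
heads, feed-forward width 2048, output dimension 512, Adam with initial
learning rate 1e-4 and batch size 32.  The desk-scale defaults below are the
toy configuration exercised by the tests.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .embedder import ResidueEmbeddings

__all__ = [
    "EncoderConfig",
    "ProteinVector",
    "PairRecord",
    "TMVecEncoder",
    "TrainingLog",
    "encode_protein",
    "predict_tm",
    "cosine",
    "train_tmvec",
]


@dataclass(frozen=True)
class EncoderConfig:
    """phi hyperparameters (reference scale in parentheses).

    n_transformer_layers -- encoder blocks (2-4); n_heads -- attention heads
    (4); ff_dim -- feed-forward width (2048); d_in -- residue embedding
    dimension (1024); out_dim -- protein-vector dimension (512); dropout --
    rate applied after pooling during training only.
    """

    n_transformer_layers: int = 1
    n_heads: int = 2
    ff_dim: int = 32
    d_in: int = 16
    out_dim: int = 8
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_transformer_layers, self.n_heads, self.ff_dim, self.d_in, self.out_dim) < 1:
            raise ValueError("all sizes must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class ProteinVector:
    """Structure-aware embedding; cosine similarity predicts the TM-score."""

    z: np.ndarray
    sequence_id: str = ""
    model_hash: str = ""

    def __post_init__(self):
        z = np.ascontiguousarray(np.asarray(self.z, dtype=np.float64))
        object.__setattr__(self, "z", z)
        if z.ndim != 1 or not np.isfinite(z).all():
            raise ValueError("protein vector must be a finite 1-D array")


@dataclass(frozen=True)
class PairRecord:
    """One labeled training pair: ids plus a similarity label in [0, 1]."""

    id_a: str
    id_b: str
    label: float
    split: str = ""

    def __post_init__(self):
        if not (0.0 <= self.label <= 1.0):
            raise ValueError(f"label {self.label} outside [0, 1] for ({self.id_a}, {self.id_b})")


def params_hash(state: dict[str, np.ndarray]) -> str:
    """Content hash of a parameter set (float32 little-endian bytes)."""
    h = hashlib.sha256()
    for name in sorted(state):
        h.update(name.encode())
        h.update(np.ascontiguousarray(state[name], dtype="<f4").tobytes())
    return h.hexdigest()[:16]


class TMVecEncoder(nn.Module):
    """The twin network phi."""

    def __init__(self, config: EncoderConfig = EncoderConfig()):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.layers = [
            nn.TransformerEncoderLayer(config.d_in, config.n_heads, config.ff_dim, rng)
            for _ in range(config.n_transformer_layers)
        ]
        # pooled representation -> one hidden layer -> linear projection
        self.fc1 = nn.Linear(config.d_in, config.out_dim, rng)
        self.fc2 = nn.Linear(config.out_dim, config.out_dim, rng)

    def forward(self, vectors: np.ndarray, train_rng: np.random.Generator | None = None) -> nn.Tensor:
        """Encode one (length x d_in) embedding matrix to an out_dim vector.

        ``train_rng`` enables dropout; inference (None) is deterministic.
        Sequences are processed individually at their true length, so there
        are no padded positions and pooling is over real residues only.
        """
        if vectors.shape[1] != self.config.d_in:
            raise ValueError(
                f"embedding dimension {vectors.shape[1]} != d_in {self.config.d_in}"
            )
        x = nn.constant(vectors)
        for layer in self.layers:
            x = layer(x)
        pooled = x.mean(axis=0)
        pooled = nn.dropout(pooled, self.config.dropout, train_rng)
        # tanh keeps the hidden representation sign-symmetric, which suits a
        # cosine-similarity output better than a rectifier
        return self.fc2(self.fc1(pooled).tanh())

    @property
    def model_hash(self) -> str:
        return params_hash(self.state_dict())


def encode_protein(emb: ResidueEmbeddings, model: TMVecEncoder) -> ProteinVector:
    """Deterministic inference-mode encoding of one protein."""
    z = model.forward(emb.vectors, train_rng=None).data
    return ProteinVector(z=z, sequence_id=emb.sequence_id, model_hash=model.model_hash)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-norm vector in cosine similarity")
    return float(np.dot(a, b) / (na * nb))


def predict_tm(za: ProteinVector, zb: ProteinVector, clamp: bool = True) -> float:
    """Predicted TM-score = cosine similarity of the two protein vectors.

    Symmetric in its arguments; the raw cosine lies in [-1, 1] and is clamped
    to [0, 1] for reporting (pass clamp=False for the raw value)."""
    if za.z.shape != zb.z.shape:
        raise ValueError("protein vectors have different dimensions")
    if za.model_hash and zb.model_hash and za.model_hash != zb.model_hash:
        raise ValueError("protein vectors come from different models")
    c = cosine(za.z, zb.z)
    return min(1.0, max(0.0, c)) if clamp else c


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = math.inf


def _resolve_embeddings(ids, sequences, embedder) -> dict[str, np.ndarray]:
    cache: dict[str, np.ndarray] = {}
    for sid in ids:
        if sid in cache:
            continue
        if sid not in sequences:
            raise KeyError(f"pair references unknown sequence id {sid!r}")
        cache[sid] = embedder(sequences[sid], sequence_id=sid).vectors
    return cache


def train_tmvec(
    pairs: list[PairRecord],
    sequences: dict[str, str],
    config: EncoderConfig = EncoderConfig(),
    embedder=None,
    lr: float = 1e-4,
    batch_size: int = 32,
    epochs: int = 20,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[TMVecEncoder, TrainingLog]:
    """Train phi to regress cosine similarity onto pair labels (L1 loss, Adam).

    Pairs with split tags 'train'/'val' are honored; untagged pairs are split
    randomly with ``val_fraction``.  The best-validation parameter snapshot
    is restored before returning.  Fully seeded and single-threaded, so two
    runs with the same inputs produce identical loss curves.
    """
    if embedder is None:
        from .embedder import ToyEmbedder

        embedder = ToyEmbedder(d=config.d_in, seed=0)
    if not pairs:
        raise ValueError("empty pair set")
    rng = np.random.default_rng(seed)
    ids = {p.id_a for p in pairs} | {p.id_b for p in pairs}
    emb = _resolve_embeddings(sorted(ids), sequences, embedder)

    tagged = any(p.split for p in pairs)
    if tagged:
        train = [p for p in pairs if p.split != "val"]
        val = [p for p in pairs if p.split == "val"]
    else:
        order = rng.permutation(len(pairs))
        n_val = int(round(val_fraction * len(pairs)))
        val = [pairs[i] for i in order[:n_val]]
        train = [pairs[i] for i in order[n_val:]]
    if not train or (val_fraction > 0 and not val):
        raise ValueError("a train/validation split is empty")

    model = TMVecEncoder(config)
    opt = nn.Adam(model.parameters(), lr=lr)
    log = TrainingLog()
    best_state = nn.snapshot(model)

    def _pair_loss(p: PairRecord, train_rng):
        za = model.forward(emb[p.id_a], train_rng)
        zb = model.forward(emb[p.id_b], train_rng)
        return nn.absval(nn.cosine_similarity(za, zb) - p.label)

    for epoch in range(epochs):
        order = rng.permutation(len(train))
        total = 0.0
        for start in range(0, len(order), batch_size):
            batch = [train[i] for i in order[start : start + batch_size]]
            opt.zero_grad()
            loss = None
            for p in batch:
                term = _pair_loss(p, rng)
                loss = term if loss is None else loss + term
            loss = loss * (1.0 / len(batch))
            loss.backward()
            opt.step()
            total += loss.item() * len(batch)
        log.train_loss.append(total / len(train))
        vloss = (
            float(np.mean([_pair_loss(p, None).item() for p in val])) if val else math.nan
        )
        log.val_loss.append(vloss)
        if val and vloss < log.best_val_loss:
            log.best_val_loss = vloss
            log.best_epoch = epoch
            best_state = nn.snapshot(model)
    if val:
        model.load_state_dict(best_state)
    return model, log
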