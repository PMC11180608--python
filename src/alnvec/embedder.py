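"""Per-residue embedding backends.

Protein language models map a residue string to a matrix of per-residue
vectors (length x d); downstream components only see that matrix, so the
backend is pluggable.  The built-in ``toy`` backend is a deterministic,
seed-fixed stand-in used throughout the test fixtures: one-hot residue
identity projected through a fixed random matrix and averaged over a small
local window, so that nearby residues correlate and homologous positions in
related sequences receive similar vectors.  An external model can be
registered at run time via :func:`register_backend`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from Bio import SeqIO

__all__ = [
    "ResidueEmbeddings",
    "ToyEmbedder",
    "embed_residues",
    "get_embedder",
    "register_backend",
    "read_fasta",
    "write_fasta",
    "MAX_SEQUENCE_LENGTH",
    "ALPHABET",
]

# 20 standard residues; anything else (X/B/Z/U/O/J, ...) maps to a dedicated
# "unknown" channel, index 20.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CODE = {aa: i for i, aa in enumerate(ALPHABET)}
UNKNOWN = len(ALPHABET)

# default maximum input length, mirroring length-filtered training corpora
MAX_SEQUENCE_LENGTH = 1000


@dataclass(frozen=True)
class ResidueEmbeddings:
    """Length x d matrix of per-residue vectors for one sequence."""

    vectors: np.ndarray
    sequence_id: str = ""

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vectors, dtype=np.float64))
        object.__setattr__(self, "vectors", v)
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError("embeddings must be a (length >= 1) x d matrix")
        if not np.isfinite(v).all():
            raise ValueError("embeddings must be finite")

    @property
    def length(self) -> int:
        return self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


def encode_sequence(sequence: str) -> np.ndarray:
    """Integer codes in [0, 20] for a residue string (21 = unknown channel)."""
    if not sequence:
        raise ValueError("empty sequence")
    return np.array([_CODE.get(c, UNKNOWN) for c in sequence.upper()], dtype=np.int64)


class ToyEmbedder:
    """Deterministic hash-seeded embedder for offline tests.

    Two kinds of context-aware channels, both fixed by the seed:

    * windowed-mean channels -- each residue identity owns a random vector
      (row of a seeded 21 x d projection of one-hot identities); position i
      receives the mean over the window [i-window, i+window], so nearby
      residues correlate and a single substitution perturbs its
      neighborhood only partially.
    * k-mer-hash channels (``hash_dim`` > 0) -- position i receives a random
      vector seeded by a CRC hash of its local k-mer
      seq[i-hash_window : i+hash_window+1]; conserved windows in two
      sequences get *identical* vectors while any mutation decorrelates
      them completely, so pooled inner products count shared k-mers.

    The output is the concatenation (d - hash_dim windowed-mean channels
    followed by hash_dim hash channels); ``hash_dim=0`` (default) is the
    pure windowed-mean embedder.
    """

    name = "toy"

    def __init__(
        self,
        d: int = 16,
        seed: int = 0,
        window: int = 2,
        hash_dim: int = 0,
        hash_window: int = 1,
    ):
        if d < 1 or window < 0 or not (0 <= hash_dim <= d) or hash_window < 0:
            raise ValueError("need d >= 1, window >= 0, 0 <= hash_dim <= d")
        if hash_dim == d and d > 0:
            self.mean_dim = 0
        else:
            self.mean_dim = d - hash_dim
        self.d = d
        self.seed = seed
        self.window = window
        self.hash_dim = hash_dim
        self.hash_window = hash_window
        rng = np.random.default_rng(seed)
        self._proj = rng.normal(0.0, 1.0, size=(UNKNOWN + 1, max(self.mean_dim, 1)))
        self._kmer_cache: dict[str, np.ndarray] = {}

    def _hash_vector(self, kmer: str) -> np.ndarray:
        v = self._kmer_cache.get(kmer)
        if v is None:
            import zlib

            s = (zlib.crc32(kmer.encode()) ^ (self.seed & 0xFFFFFFFF)) & 0xFFFFFFFF
            v = np.random.default_rng(s).normal(0.0, 1.0, self.hash_dim)
            self._kmer_cache[kmer] = v
        return v

    def __call__(self, sequence: str, sequence_id: str = "") -> ResidueEmbeddings:
        codes = encode_sequence(sequence)
        L = len(codes)
        parts = []
        if self.mean_dim:
            base = self._proj[codes]  # L x mean_dim
            w = self.window
            mean_part = np.empty((L, self.mean_dim))
            csum = np.zeros((L + 1, self.mean_dim))
            np.cumsum(base, axis=0, out=csum[1:])
            for i in range(L):
                lo, hi = max(0, i - w), min(L, i + w + 1)
                mean_part[i] = (csum[hi] - csum[lo]) / (hi - lo)
            parts.append(mean_part)
        if self.hash_dim:
            seq = "".join("ACDEFGHIKLMNPQRSTVWYU"[c] for c in codes)
            hw = self.hash_window
            hash_part = np.empty((L, self.hash_dim))
            for i in range(L):
                hash_part[i] = self._hash_vector(seq[max(0, i - hw) : i + hw + 1])
            parts.append(hash_part)
        out = parts[0] if len(parts) == 1 else np.hstack(parts)
        return ResidueEmbeddings(vectors=out, sequence_id=sequence_id)


_BACKENDS: dict[str, Callable[..., object]] = {"toy": ToyEmbedder}


def register_backend(name: str, factory: Callable[..., object]) -> None:
    """Register an external embedder factory (e.g. a pretrained model adapter)."""
    _BACKENDS[name] = factory


def get_embedder(backend: str = "toy", **params):
    """Instantiate an embedder by name; external adapters use 'external:<name>'."""
    key = backend.split(":", 1)[-1] if backend.startswith("external:") else backend
    if key not in _BACKENDS:
        raise ValueError(f"unknown embedder backend {backend!r}")
    return _BACKENDS[key](**params)


def embed_residues(
    sequence: str,
    backend="toy",
    sequence_id: str = "",
    max_length: int = MAX_SEQUENCE_LENGTH,
    allow_long: bool = False,
    **params,
) -> ResidueEmbeddings:
    """Embed one sequence with the selected backend.

    ``backend`` may be a backend name or an already-instantiated embedder.
    Sequences longer than ``max_length`` are rejected unless ``allow_long``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if len(sequence) > max_length and not allow_long:
        raise ValueError(
            f"sequence {sequence_id or '<unnamed>'} has length {len(sequence)} "
            f"> {max_length}; pass allow_long=True to override"
        )
    emb = backend if callable(backend) else get_embedder(backend, **params)
    return emb(sequence, sequence_id=sequence_id)


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly line-wrapped, multi-record) FASTA; '*' stops stripped."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).replace("*", "").upper()
    return out


def write_fasta(path, records: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
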