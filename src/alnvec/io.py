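"""Checkpoints and tabular file formats.

Checkpoint format: a single ``.npz`` archive holding named little-endian
float32 parameter arrays under ``param/<name>`` plus a ``__meta__`` JSON
string with a forward-compatible version field, the model kind, its config,
the training seed and a content hash of the parameter bytes.

Tabular formats are plain TSV: pair tables (id_a, id_b, label[, split]),
alignment tables (id_a, id_b, states, label), annotation tables (id, label),
hit tables (query_id, hit_id, rank, predicted_tm) and vector tables
(id, v0..v{d-1}).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .scoring_heads import ScoringHeadConfig, ScoringHeads
from .tmvec_encoder import EncoderConfig, PairRecord, TMVecEncoder, params_hash
from .vector_index import SearchHit

__all__ = [
    "save_checkpoint",
    "load_checkpoint",
    "save_tmvec",
    "load_tmvec",
    "save_heads",
    "load_heads",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "read_alignments_tsv",
    "write_alignments_tsv",
    "read_annotations_tsv",
    "write_annotations_tsv",
    "read_hits_tsv",
    "write_hits_tsv",
    "read_vectors_tsv",
    "write_vectors_tsv",
]

CHECKPOINT_VERSION = 1


def save_checkpoint(
    path, state: dict[str, np.ndarray], config: dict, seed: int, kind: str,
    embedder_info: dict | None = None,
) -> str:
    """Write a model checkpoint; returns the content hash."""
    h = params_hash(state)
    meta = {
        "format_version": CHECKPOINT_VERSION,
        "kind": kind,
        "config": config,
        "seed": seed,
        "model_hash": h,
        "embedder": embedder_info or {},
    }
    arrays = {f"param/{k}": np.ascontiguousarray(v, dtype="<f4") for k, v in state.items()}
    np.savez(path, __meta__=np.asarray(json.dumps(meta)), **arrays)
    return h


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {
            k[len("param/") :]: z[k].astype(np.float64)
            for k in z.files
            if k.startswith("param/")
        }
    if meta.get("format_version", 0) > CHECKPOINT_VERSION:
        raise ValueError("checkpoint written by a newer format version")
    return state, meta


def save_tmvec(path, model: TMVecEncoder, seed: int = 0, embedder_info: dict | None = None) -> str:
    return save_checkpoint(
        path, model.state_dict(), vars(model.config) | {}, seed, "tmvec", embedder_info
    )


def load_tmvec(path) -> TMVecEncoder:
    state, meta = load_checkpoint(path)
    if meta["kind"] != "tmvec":
        raise ValueError(f"not a tmvec checkpoint: kind={meta['kind']!r}")
    cfg = EncoderConfig(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in meta["config"].items()})
    model = TMVecEncoder(cfg)
    model.load_state_dict(state)
    return model


def save_heads(path, heads: ScoringHeads, seed: int = 0, embedder_info: dict | None = None) -> str:
    return save_checkpoint(
        path, heads.state_dict(), vars(heads.config) | {}, seed, "deepblast", embedder_info
    )


def load_heads(path) -> ScoringHeads:
    state, meta = load_checkpoint(path)
    if meta["kind"] != "deepblast":
        raise ValueError(f"not a scoring-heads checkpoint: kind={meta['kind']!r}")
    heads = ScoringHeads(ScoringHeadConfig(**meta["config"]))
    heads.load_state_dict(state)
    return heads


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def _read_table(path, expected_header: list[str]) -> list[list[str]]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path} is empty")
    header = lines[0].split("\t")
    if header[: len(expected_header)] != expected_header:
        raise ValueError(f"{path}: expected columns {expected_header}, found {header}")
    return [line.split("\t") for line in lines[1:] if line.strip()]


def read_pairs_tsv(path) -> list[PairRecord]:
    rows = _read_table(path, ["id_a", "id_b", "label"])
    return [
        PairRecord(id_a=r[0], id_b=r[1], label=float(r[2]), split=r[3] if len(r) > 3 else "")
        for r in rows
    ]


def write_pairs_tsv(path, pairs: list[PairRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tlabel\tsplit\n")
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.label:.6f}\t{p.split}\n")


def read_alignments_tsv(path) -> list[tuple[str, str, str, float]]:
    rows = _read_table(path, ["id_a", "id_b", "states", "label"])
    return [(r[0], r[1], r[2], float(r[3])) for r in rows]


def write_alignments_tsv(path, rows: list[tuple[str, str, str, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tstates\tlabel\n")
        for ida, idb, states, label in rows:
            fh.write(f"{ida}\t{idb}\t{states}\t{label:.6f}\n")


def read_annotations_tsv(path) -> dict[str, set[str]]:
    rows = _read_table(path, ["id", "label"])
    out: dict[str, set[str]] = {}
    for r in rows:
        out.setdefault(r[0], set()).add(r[1])
    return out


def write_annotations_tsv(path, annotations: dict[str, str | set[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for sid in sorted(annotations):
            labs = annotations[sid]
            for lab in sorted({labs} if isinstance(labs, str) else labs):
                fh.write(f"{sid}\t{lab}\n")


def write_hits_tsv(path, hits: list[list[SearchHit]]) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\thit_id\trank\tpredicted_tm\n")
        for hit_list in hits:
            for h in hit_list:
                fh.write(f"{h.query_id}\t{h.hit_id}\t{h.rank}\t{h.predicted_tm:.6f}\n")


def read_hits_tsv(path) -> dict[str, list[SearchHit]]:
    rows = _read_table(path, ["query_id", "hit_id", "rank", "predicted_tm"])
    out: dict[str, list[SearchHit]] = {}
    for r in rows:
        out.setdefault(r[0], []).append(
            SearchHit(query_id=r[0], hit_id=r[1], rank=int(r[2]), predicted_tm=float(r[3]))
        )
    for hl in out.values():
        hl.sort(key=lambda h: h.rank)
    return out


def write_vectors_tsv(path, ids: list[str], vectors: np.ndarray) -> None:
    vectors = np.asarray(vectors)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(f"v{i}" for i in range(vectors.shape[1])) + "\n")
        for sid, row in zip(ids, vectors):
            fh.write(sid + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")


def read_vectors_tsv(path) -> tuple[list[str], np.ndarray]:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("id\t"):
        raise ValueError(f"{path} is not a vectors TSV")
    ids, rows = [], []
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return ids, np.asarray(rows, dtype=np.float64)
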