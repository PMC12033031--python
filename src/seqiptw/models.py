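"""Deep sequence propensity models: LSTM, BERT_code and BERT_record.

All three map a patient's ordered records directly to an estimated
propensity score, with no hand-built features:

* **LSTM** — each record is represented by the average of its code
  embeddings (empty records give a zero vector); the record representations
  are fed through an LSTM and a sigmoid head reads the final non-padded
  hidden state.
* **BERT_code** — one input token per code occurrence, arranged
  chronologically after a leading [CLS] token; all codes of record t share
  sinusoidal positional encoding at position t ([CLS] sits at position 0).
  Within a record, tokens are ordered by ascending vocabulary index (records
  are bags, so the order is a reproducibility convention, not information).
* **BERT_record** — one averaged-pool token per record after [CLS],
  positions 0..T.

Both BERT variants read the last-layer [CLS] representation through a
sigmoid head.  Training minimizes cross-entropy between the estimated
propensity and the binary treatment label (Adam, no LR scheduling), with
early stopping on validation cross-entropy.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np

from .data import ClaimsDataset, PatientSequence
from .nn import (
    Adam,
    Dense,
    LSTMCellBank,
    Module,
    Tensor,
    TransformerEncoderLayer,
    bce_with_logits,
)

__all__ = [
    "SeqModelConfig",
    "ModelInput",
    "positional_encoding",
    "record_representation",
    "build_bert_code_input",
    "build_bert_record_input",
    "LSTMPropensity",
    "BertPropensity",
    "make_model",
    "forward_propensity",
    "train_sequence_model",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-7

KINDS = ("lstm", "bert_code", "bert_record")


@dataclass(frozen=True)
class SeqModelConfig:
    kind: str = "lstm"
    embed_dim: int = 64
    hidden_dim: int = 64      # LSTM
    n_layers: int = 2         # BERT
    n_heads: int = 4
    ff_dim: int = 128
    dropout: float = 0.1
    max_seq_len: int = 512
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 50
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; one of {KINDS}")
        if self.embed_dim % 2 != 0:
            raise ValueError("embed_dim must be even (sine/cosine pairing)")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("n_heads must divide embed_dim")


@dataclass
class ModelInput:
    """One patient's encoder input before embedding.

    ``token_features`` has one row per token over the vocabulary: a one-hot
    row per code occurrence (BERT_code) or a normalized multi-hot row per
    record (BERT_record); the [CLS] row is all-zero (its embedding is a
    dedicated learned vector).  ``positions`` holds the positional-encoding
    index of every token, [CLS] first at position 0.
    """

    token_features: np.ndarray  # (L, dx)
    positions: np.ndarray       # (L,)

    @property
    def length(self) -> int:
        return self.token_features.shape[0]


def positional_encoding(pos: int, dim: int) -> np.ndarray:
    """Sinusoidal encoding: element 2i = sin(pos/10000^(2i/dim)),
    element 2i+1 = cos(pos/10000^(2i/dim))."""
    if dim % 2 != 0:
        raise ValueError("dim must be even")
    i = np.arange(dim // 2)
    angle = pos / (10000.0 ** (2.0 * i / dim))
    pe = np.empty(dim)
    pe[0::2] = np.sin(angle)
    pe[1::2] = np.cos(angle)
    return pe


def _pe_table(max_pos: int, dim: int) -> np.ndarray:
    return np.stack([positional_encoding(p, dim) for p in range(max_pos + 1)])


def record_representation(code_indices, embedding_table: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the record's code embeddings; empty -> zero vector."""
    idx = sorted(code_indices)
    if not idx:
        return np.zeros(embedding_table.shape[1])
    return embedding_table[idx].mean(axis=0)


def build_bert_code_input(seq: PatientSequence, dx: int, max_seq_len: int = 512) -> ModelInput:
    """[CLS] then one token per code occurrence in chronological record order.

    Empty records contribute no tokens but still advance the position counter.
    """
    rows = [np.zeros(dx)]  # [CLS]
    positions = [0]
    for r in seq.records:
        for c in sorted(r.codes):
            row = np.zeros(dx)
            row[c] = 1.0
            rows.append(row)
            positions.append(r.t)
    if len(rows) > max_seq_len:
        raise ValueError(
            f"patient {seq.id}: input length {len(rows)} exceeds max_seq_len={max_seq_len}"
        )
    return ModelInput(np.array(rows), np.array(positions))


def build_bert_record_input(seq: PatientSequence, dx: int, max_seq_len: int = 512) -> ModelInput:
    """[CLS] then one averaged-pool token per record, positions 0..T."""
    if seq.T + 1 > max_seq_len:
        raise ValueError(
            f"patient {seq.id}: input length {seq.T + 1} exceeds max_seq_len={max_seq_len}"
        )
    rows = [np.zeros(dx)]
    positions = [0]
    for r in seq.records:
        row = np.zeros(dx)
        if r.codes:
            row[sorted(r.codes)] = 1.0 / len(r.codes)  # mean of code embeddings
        rows.append(row)
        positions.append(r.t)
    return ModelInput(np.array(rows), np.array(positions))


def _pad_batch(inputs: list[ModelInput], dx: int):
    B = len(inputs)
    L = max(inp.length for inp in inputs)
    feats = np.zeros((B, L, dx))
    positions = np.zeros((B, L), dtype=np.int64)
    mask = np.zeros((B, L), dtype=bool)
    for i, inp in enumerate(inputs):
        n = inp.length
        feats[i, :n] = inp.token_features
        positions[i, :n] = inp.positions
        mask[i, :n] = True
    return feats, positions, mask


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


class _PropensityBase(Module):
    cfg: SeqModelConfig
    dx: int

    def compute_batch(self) -> int:
        """Largest batch the numpy engine handles efficiently: BERT_code
        attention tensors grow as (batch x heads x L^2) with L ~ total codes,
        so its batches are capped at 32."""
        if self.cfg.kind == "bert_code":
            return min(self.cfg.batch_size, 32)
        return self.cfg.batch_size

    def predict(self, data, batch_size: int | None = None) -> np.ndarray:
        seqs = data.patients if isinstance(data, ClaimsDataset) else list(data)
        bs = batch_size or self.compute_batch()
        rng = np.random.default_rng(0)  # dropout off: unused
        out = []
        for start in range(0, len(seqs), bs):
            logits = self.forward(seqs[start : start + bs], rng, training=False)
            out.append(1.0 / (1.0 + np.exp(-logits.data.ravel())))
        return np.clip(np.concatenate(out), _EPS, 1.0 - _EPS)


class LSTMPropensity(_PropensityBase):
    def __init__(self, cfg: SeqModelConfig, dx: int):
        rng = np.random.default_rng(cfg.seed)
        self.cfg, self.dx = cfg, dx
        D = cfg.embed_dim
        self.embedding = Tensor(rng.normal(0, 0.1, size=(dx, D)), requires_grad=True)
        self.lstm = LSTMCellBank(D, cfg.hidden_dim, rng)
        self.head = Dense(cfg.hidden_dim, 1, rng)

    def forward(self, seqs: list[PatientSequence], rng, training: bool) -> Tensor:
        B = len(seqs)
        Tmax = max(s.T for s in seqs)
        # normalized multi-hot per record: row @ embedding == mean code embedding
        R = np.zeros((B, Tmax, self.dx))
        select = np.zeros((B, 1, Tmax))  # picks the final non-padded hidden state
        for i, s in enumerate(seqs):
            for r in s.records:
                if r.codes:
                    R[i, r.t - 1, sorted(r.codes)] = 1.0 / len(r.codes)
            select[i, 0, s.T - 1] = 1.0
        x = Tensor(R) @ self.embedding
        hs = self.lstm(x)
        h_last = (Tensor(select) @ hs).reshape(B, self.cfg.hidden_dim)
        return self.head(h_last).reshape(B)


class BertPropensity(_PropensityBase):
    def __init__(self, cfg: SeqModelConfig, dx: int):
        if cfg.kind not in ("bert_code", "bert_record"):
            raise ValueError("BertPropensity needs kind bert_code or bert_record")
        rng = np.random.default_rng(cfg.seed)
        self.cfg, self.dx = cfg, dx
        D = cfg.embed_dim
        self.embedding = Tensor(rng.normal(0, 0.1, size=(dx, D)), requires_grad=True)
        self.cls = Tensor(rng.normal(0, 0.1, size=(D,)), requires_grad=True)
        self.layers = [
            TransformerEncoderLayer(D, cfg.n_heads, cfg.ff_dim, cfg.dropout, rng)
            for _ in range(cfg.n_layers)
        ]
        self.head = Dense(D, 1, rng)
        self._pe_cache = _pe_table(64, D)

    def build_input(self, seq: PatientSequence) -> ModelInput:
        if self.cfg.kind == "bert_code":
            return build_bert_code_input(seq, self.dx, self.cfg.max_seq_len)
        return build_bert_record_input(seq, self.dx, self.cfg.max_seq_len)

    def forward(self, seqs: list[PatientSequence], rng, training: bool) -> Tensor:
        inputs = [self.build_input(s) for s in seqs]
        feats, positions, mask = _pad_batch(inputs, self.dx)
        B, L, _ = feats.shape
        if positions.max() >= self._pe_cache.shape[0]:
            self._pe_cache = _pe_table(int(positions.max()), self.cfg.embed_dim)
        cls_indicator = np.zeros((L, 1))
        cls_indicator[0, 0] = 1.0
        x = (
            Tensor(feats) @ self.embedding
            + Tensor(cls_indicator) * self.cls
            + Tensor(self._pe_cache[positions] * mask[:, :, None])
        )
        for layer in self.layers:
            x = layer(x, mask, rng, training)
        return self.head(x[:, 0, :]).reshape(B)

    def attention_maps(self) -> list[np.ndarray]:
        """Per-layer (B, heads, L, L) row-stochastic maps from the last forward."""
        return [layer.attn.last_attention for layer in self.layers]


def make_model(cfg: SeqModelConfig, dx: int) -> _PropensityBase:
    if cfg.kind == "lstm":
        return LSTMPropensity(cfg, dx)
    return BertPropensity(cfg, dx)


def forward_propensity(model: _PropensityBase, seqs, return_attention: bool = False):
    """Estimated propensities for a batch; optionally the attention maps."""
    rng = np.random.default_rng(0)
    logits = model.forward(list(seqs), rng, training=False)
    e = np.clip(1.0 / (1.0 + np.exp(-logits.data.ravel())), _EPS, 1.0 - _EPS)
    if return_attention:
        if not isinstance(model, BertPropensity):
            raise TypeError("attention maps are only available for BERT models")
        return e, model.attention_maps()
    return e


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _cross_entropy(e: np.ndarray, A: np.ndarray) -> float:
    e = np.clip(e, _EPS, 1.0 - _EPS)
    return float(-np.mean(A * np.log(e) + (1 - A) * np.log(1 - e)))


def train_sequence_model(
    cfg: SeqModelConfig,
    train_ds: ClaimsDataset,
    val_ds: ClaimsDataset | None = None,
    val_fraction: float = 0.1,
):
    """Fit a sequence propensity model with early stopping.

    Returns ``(model, log)`` where ``log`` is a list of per-epoch dicts with
    train/validation cross-entropy.  If no validation set is given, a
    ``val_fraction`` split is carved from the training data (seeded).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    seqs = list(train_ds.patients)
    if val_ds is None:
        idx = rng.permutation(len(seqs))
        n_val = max(1, int(len(seqs) * val_fraction))
        val_seqs = [seqs[i] for i in idx[:n_val]]
        seqs = [seqs[i] for i in idx[n_val:]]
    else:
        val_seqs = list(val_ds.patients)
    A_train = np.array([p.A for p in seqs], dtype=np.float64)
    A_val = np.array([p.A for p in val_seqs], dtype=np.float64)
    if len(set(A_train)) < 2:
        raise ValueError("training data must contain both treatment classes")

    model = make_model(cfg, train_ds.vocabulary.size)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    best_state, best_val, best_epoch = model.state_dict(), np.inf, -1
    log: list[dict] = []
    n = len(seqs)
    bs = model.compute_batch()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, bs):
            batch_idx = order[start : start + bs]
            batch = [seqs[i] for i in batch_idx]
            logits = model.forward(batch, rng, training=True)
            loss = bce_with_logits(logits, A_train[batch_idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged (loss={loss.data}) at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val_ce = _cross_entropy(model.predict(val_seqs), A_val)
        log.append(
            {"epoch": epoch, "train_ce": epoch_loss / max(n_batches, 1), "val_ce": val_ce}
        )
        if val_ce < best_val - 1e-6:
            best_val, best_state, best_epoch = val_ce, model.state_dict(), epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    model.load_state_dict(best_state)
    return model, log


def save_checkpoint(model: _PropensityBase, path, log=None) -> None:
    payload = {
        "config": model.cfg,
        "dx": model.dx,
        "state": model.state_dict(),
        "log": log or [],
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    model = make_model(payload["config"], payload["dx"])
    model.load_state_dict(payload["state"])
    return model, payload["log"]
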