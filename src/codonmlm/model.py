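"""The dual-stream masked-LM encoder.

Two token streams run through the network in lock-step, one position per
residue: an amino-acid stream and a codon stream.  Each encoder block
applies self-attention within each stream, then cross-attention in which
the amino-acid states are the queries and the codon states supply both the
keys and the values, then a position-wise feed-forward on each stream —
residual connections and layer normalisation around every sublayer.

The codon prediction head reads the amino-acid (query) stream's final
states — the protein positions are what must emit codons — while the
amino-acid head reads the codon stream's final states.

Whole-sequence hiding is implemented at the embedding output: a
"sequence-zeroed" batch row replaces its entire codon-stream embedding
(token and position) with zeros, the placeholder encoding the model sees
at inference time when predicting codons from protein alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .datasets import TranscriptRecord
from .errors import ConfigError
from .seqcore import AMINO_ACIDS, CODONS

# ---------------------------------------------------------------------------
# Vocabularies: PAD=0, MASK=1, then the tokens in lexicographic order
# ---------------------------------------------------------------------------

PAD_ID = 0
MASK_ID = 1
IGNORE_INDEX = -100

CODON_TO_ID = {c: i + 2 for i, c in enumerate(CODONS)}
ID_TO_CODON = {i: c for c, i in CODON_TO_ID.items()}
AA_TO_ID = {a: i + 2 for i, a in enumerate(AMINO_ACIDS)}
ID_TO_AA = {i: a for a, i in AA_TO_ID.items()}

CODON_VOCAB = 2 + len(CODONS)  # 66
AA_VOCAB = 2 + len(AMINO_ACIDS)  # 22


@dataclass(frozen=True)
class ModelConfig:
    embed_dim: int = 64
    n_blocks: int = 2
    n_heads: int = 4
    ff_dim: int = 128
    max_len: int = 128
    dropout: float = 0.0
    codon_vocab: int = CODON_VOCAB
    aa_vocab: int = AA_VOCAB

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ConfigError("embed_dim must be divisible by n_heads")
        if self.max_len < 1 or self.n_blocks < 0:
            raise ConfigError("max_len and n_blocks must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must lie in [0, 1)")

    @classmethod
    def tiny(cls, max_len: int = 128) -> "ModelConfig":
        """Desk-scale preset used throughout the test battery."""
        return cls(embed_dim=64, n_blocks=2, n_heads=4, ff_dim=128, max_len=max_len)

    @classmethod
    def large(cls, max_len: int = 2048) -> "ModelConfig":
        """A bigger preset for real corpora; sizes are this package's
        choices, not taken from any external study."""
        return cls(embed_dim=256, n_blocks=6, n_heads=8, ff_dim=1024, max_len=max_len)


@dataclass
class Batch:
    """Paired token grids plus masking state.

    ``pad_mask`` is True at real positions.  Labels use IGNORE_INDEX at
    positions that do not contribute to the loss.  ``seq_zeroed`` marks
    rows whose codon stream is replaced by the all-zero placeholder.
    """

    aa_ids: np.ndarray
    codon_ids: np.ndarray
    pad_mask: np.ndarray
    codon_labels: np.ndarray
    aa_labels: np.ndarray
    seq_zeroed: np.ndarray

    def __post_init__(self) -> None:
        if not (
            self.aa_ids.shape
            == self.codon_ids.shape
            == self.pad_mask.shape
            == self.codon_labels.shape
            == self.aa_labels.shape
        ):
            raise ConfigError("batch grids must share one (batch, length) shape")
        if self.seq_zeroed.shape != (self.aa_ids.shape[0],):
            raise ConfigError("seq_zeroed must be one flag per batch row")

    @property
    def size(self) -> int:
        return self.aa_ids.shape[0]

    @property
    def length(self) -> int:
        return self.aa_ids.shape[1]

    def copy(self) -> "Batch":
        return Batch(
            aa_ids=self.aa_ids.copy(),
            codon_ids=self.codon_ids.copy(),
            pad_mask=self.pad_mask.copy(),
            codon_labels=self.codon_labels.copy(),
            aa_labels=self.aa_labels.copy(),
            seq_zeroed=self.seq_zeroed.copy(),
        )


def make_batch(records: Sequence[TranscriptRecord], max_len: Optional[int] = None) -> Batch:
    """Tokenize records into a padded batch; position i of both streams
    refers to the same residue/codon."""
    lengths = [len(r.protein) for r in records]
    pad_to = max(lengths)
    if max_len is not None and pad_to > max_len:
        raise ConfigError(f"sequence length {pad_to} exceeds max_len {max_len}")
    n = len(records)
    aa_ids = np.full((n, pad_to), PAD_ID, dtype=np.int64)
    codon_ids = np.full((n, pad_to), PAD_ID, dtype=np.int64)
    pad_mask = np.zeros((n, pad_to), dtype=bool)
    for i, r in enumerate(records):
        L = len(r.protein)
        aa_ids[i, :L] = [AA_TO_ID[a] for a in r.protein.seq]
        codon_ids[i, :L] = [CODON_TO_ID[c] for c in r.cds.coding_codons]
        pad_mask[i, :L] = True
    ignore = np.full((n, pad_to), IGNORE_INDEX, dtype=np.int64)
    return Batch(
        aa_ids=aa_ids,
        codon_ids=codon_ids,
        pad_mask=pad_mask,
        codon_labels=ignore.copy(),
        aa_labels=ignore.copy(),
        seq_zeroed=np.zeros(n, dtype=bool),
    )


@dataclass
class ModelOutput:
    codon_logits: np.ndarray
    aa_logits: np.ndarray


class DualStreamBlock:
    """One encoder block over the paired streams (post-norm residuals)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, name: str) -> None:
        d, h, f = cfg.embed_dim, cfg.n_heads, cfg.ff_dim
        self.self_aa = nn.MultiHeadAttention(d, h, rng, f"{name}.self_aa")
        self.ln_aa1 = nn.LayerNorm(d, f"{name}.ln_aa1")
        self.self_cod = nn.MultiHeadAttention(d, h, rng, f"{name}.self_cod")
        self.ln_cod1 = nn.LayerNorm(d, f"{name}.ln_cod1")
        self.cross = nn.MultiHeadAttention(d, h, rng, f"{name}.cross")
        self.ln_cross = nn.LayerNorm(d, f"{name}.ln_cross")
        self.ff_aa = nn.FeedForward(d, f, rng, f"{name}.ff_aa")
        self.ln_aa2 = nn.LayerNorm(d, f"{name}.ln_aa2")
        self.ff_cod = nn.FeedForward(d, f, rng, f"{name}.ff_cod")
        self.ln_cod2 = nn.LayerNorm(d, f"{name}.ln_cod2")
        self.drops = [nn.Dropout(cfg.dropout) for _ in range(5)]

    def forward(
        self,
        aa: np.ndarray,
        cod: np.ndarray,
        key_mask: np.ndarray,
        train: bool,
        rng: Optional[np.random.Generator],
    ) -> tuple[np.ndarray, np.ndarray]:
        d0, d1, d2, d3, d4 = self.drops
        aa1 = self.ln_aa1.forward(aa + d0.forward(self.self_aa.forward(aa, aa, key_mask), train, rng))
        cod1 = self.ln_cod1.forward(cod + d1.forward(self.self_cod.forward(cod, cod, key_mask), train, rng))
        aa2 = self.ln_cross.forward(aa1 + d2.forward(self.cross.forward(aa1, cod1, key_mask), train, rng))
        aa_out = self.ln_aa2.forward(aa2 + d3.forward(self.ff_aa.forward(aa2), train, rng))
        cod_out = self.ln_cod2.forward(cod1 + d4.forward(self.ff_cod.forward(cod1), train, rng))
        return aa_out, cod_out

    def backward(self, daa_out: np.ndarray, dcod_out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d0, d1, d2, d3, d4 = self.drops
        # codon output branch
        dcod1_sum = self.ln_cod2.backward(dcod_out)
        dcod1 = dcod1_sum + self.ff_cod.backward(d4.backward(dcod1_sum))
        # aa output branch
        daa2_sum = self.ln_aa2.backward(daa_out)
        daa2 = daa2_sum + self.ff_aa.backward(d3.backward(daa2_sum))
        # cross-attention: queries from aa1, keys/values from cod1
        daa1_sum = self.ln_cross.backward(daa2)
        dq, dkv = self.cross.backward(d2.backward(daa1_sum))
        daa1 = daa1_sum + dq
        dcod1 += dkv
        # self-attention sublayers
        dcod_sum = self.ln_cod1.backward(dcod1)
        dq_c, dkv_c = self.self_cod.backward(d1.backward(dcod_sum))
        dcod = dcod_sum + dq_c + dkv_c
        daa_sum = self.ln_aa1.backward(daa1)
        dq_a, dkv_a = self.self_aa.backward(d0.backward(daa_sum))
        daa = daa_sum + dq_a + dkv_a
        return daa, dcod

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for mod in (
            self.self_aa, self.ln_aa1, self.self_cod, self.ln_cod1,
            self.cross, self.ln_cross, self.ff_aa, self.ln_aa2,
            self.ff_cod, self.ln_cod2,
        ):
            out += mod.params()
        return out


class DualStreamEncoder:
    """The full network: embeddings, stacked blocks, two prediction heads."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.embed_dim
        self.aa_emb = nn.Embedding(config.aa_vocab, d, rng, "aa_emb")
        self.codon_emb = nn.Embedding(config.codon_vocab, d, rng, "codon_emb")
        # learned absolute positions, shared between the streams (the two
        # streams index the same residue positions)
        self.pos_emb = nn.Embedding(config.max_len, d, rng, "pos_emb")
        self.blocks = [
            DualStreamBlock(config, rng, f"block{i}") for i in range(config.n_blocks)
        ]
        self.codon_head = nn.Dense(d, config.codon_vocab, rng, "codon_head")
        self.aa_head = nn.Dense(d, config.aa_vocab, rng, "aa_head")
        self._cache = None

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        batch: Batch,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> ModelOutput:
        cfg = self.config
        if batch.length > cfg.max_len:
            raise ConfigError(f"batch length {batch.length} exceeds max_len {cfg.max_len}")
        if batch.aa_ids.max() >= cfg.aa_vocab or batch.codon_ids.max() >= cfg.codon_vocab:
            raise ConfigError("token id out of vocabulary range")
        pos = np.arange(batch.length)[None, :].repeat(batch.size, axis=0)
        pos_states = self.pos_emb.forward(pos)
        aa = self.aa_emb.forward(batch.aa_ids) + pos_states
        cod = self.codon_emb.forward(batch.codon_ids) + pos_states
        # whole-sequence hiding: zero placeholder instead of embeddings
        zero_rows = batch.seq_zeroed
        if zero_rows.any():
            cod = cod.copy()
            cod[zero_rows] = 0.0
        for blk in self.blocks:
            aa, cod = blk.forward(aa, cod, batch.pad_mask, train, rng)
        codon_logits = self.codon_head.forward(aa)
        aa_logits = self.aa_head.forward(cod)
        self._cache = (batch, zero_rows)
        return ModelOutput(codon_logits=codon_logits, aa_logits=aa_logits)

    def backward(self, dcodon_logits: np.ndarray, daa_logits: np.ndarray) -> None:
        batch, zero_rows = self._cache
        daa = self.codon_head.backward(dcodon_logits)
        dcod = self.aa_head.backward(daa_logits)
        for blk in reversed(self.blocks):
            daa, dcod = blk.backward(daa, dcod)
        if zero_rows.any():
            dcod = dcod.copy()
            dcod[zero_rows] = 0.0  # zero placeholder: no grad into codon embeds
        self.aa_emb.backward(daa)
        self.codon_emb.backward(dcod)
        self.pos_emb.backward(daa + dcod)

    def params(self) -> list[nn.Param]:
        out = self.aa_emb.params() + self.codon_emb.params() + self.pos_emb.params()
        for blk in self.blocks:
            out += blk.params()
        out += self.codon_head.params() + self.aa_head.params()
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- checkpointing ------------------------------------------------------

    CHECKPOINT_VERSION = 1

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cfg = dataclasses.asdict(self.config)
        cfg["checkpoint_version"] = self.CHECKPOINT_VERSION
        (d / "config.json").write_text(json.dumps(cfg, indent=2))
        np.savez(d / "weights.npz", **{f"p{i}": p.value for i, p in enumerate(self.params())})

    @classmethod
    def load(cls, directory: str | Path) -> "DualStreamEncoder":
        d = Path(directory)
        cfg = json.loads((d / "config.json").read_text())
        version = cfg.pop("checkpoint_version", None)
        if version != cls.CHECKPOINT_VERSION:
            raise ConfigError(f"unsupported checkpoint version {version}")
        model = cls(ModelConfig(**cfg))
        with np.load(d / "weights.npz") as data:
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"p{i}"]
        return model


def count_parameters(config: ModelConfig) -> int:
    """Closed-form parameter count, audited against the framework count."""
    d, f = config.embed_dim, config.ff_dim
    emb = (config.aa_vocab + config.codon_vocab + config.max_len) * d
    attn = 4 * (d * d + d)  # q, k, v, o projections
    ln = 2 * d
    ff = (d * f + f) + (f * d + d)
    per_block = 3 * attn + 5 * ln + 2 * ff
    heads = (d * config.codon_vocab + config.codon_vocab) + (d * config.aa_vocab + config.aa_vocab)
    return emb + config.n_blocks * per_block + heads
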