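"""Masked-LM training with the whole-sequence hiding curriculum, plus the
user-facing ``CodonModel`` / ``CodonModelResults`` pair.

The curriculum drives the model from ordinary masked-token denoising to
pure protein -> codon decoding: for the first ``warmup_epochs`` every codon
sequence is visible; thereafter, every ``step_epochs`` the fraction of
batch rows whose codon stream is replaced by the all-zero placeholder grows
by ``increment``; beyond ``full_mask_epoch`` every codon sequence is hidden
and the model trains in exactly its inference regime.

A hidden ("sequence-zeroed") row is supervised at every position — the
whole codon sequence must be reconstructed from protein alone.  Visible
rows are supervised only at randomly masked token positions, on both
streams.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .datasets import TranscriptRecord
from .errors import CodonMlmError, ConfigError
from .model import (
    IGNORE_INDEX,
    MASK_ID,
    Batch,
    DualStreamEncoder,
    ModelConfig,
    ModelOutput,
    make_batch,
)


@dataclass(frozen=True)
class CurriculumSchedule:
    """Constants of the whole-sequence hiding curriculum.

    Defaults: 15-epoch warmup, then +5% of rows hidden every 15 epochs,
    all rows hidden for epochs beyond 300.
    """

    warmup_epochs: int = 15
    step_epochs: int = 15
    increment: float = 0.05
    full_mask_epoch: int = 300

    def __post_init__(self) -> None:
        if not 0.0 < self.increment <= 1.0:
            raise ConfigError("increment must lie in (0, 1]")
        if self.warmup_epochs < 0 or self.step_epochs < 1:
            raise ConfigError("warmup must be >= 0 and step >= 1")
        if self.full_mask_epoch < self.warmup_epochs:
            raise ConfigError("full_mask_epoch must be >= warmup_epochs")

    @classmethod
    def compressed(cls) -> "CurriculumSchedule":
        """Desk-scale schedule: warmup 1, step 1, +20%/step, full by 6."""
        return cls(warmup_epochs=1, step_epochs=1, increment=0.2, full_mask_epoch=6)


def sequence_mask_fraction(epoch: int, schedule: CurriculumSchedule) -> float:
    """Fraction of batch rows whose codon sequence is hidden at ``epoch``.

    0 during warmup; min(1, increment * ceil((epoch - warmup)/step))
    afterwards; exactly 1 beyond ``full_mask_epoch``.  Monotone
    non-decreasing in epoch.
    """
    if epoch < 1:
        raise ConfigError(f"epoch must be >= 1, got {epoch}")
    if epoch <= schedule.warmup_epochs:
        return 0.0
    if epoch > schedule.full_mask_epoch:
        return 1.0
    steps = math.ceil((epoch - schedule.warmup_epochs) / schedule.step_epochs)
    return min(1.0, schedule.increment * steps)


def apply_sequence_zeroing(batch: Batch, fraction: float, rng: np.random.Generator) -> Batch:
    """Hide a uniformly sampled round(fraction * batch_size) set of rows:
    mark them sequence-zeroed and label every real position of their codon
    stream (the whole sequence must be predicted)."""
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError("fraction must lie in [0, 1]")
    out = batch.copy()
    k = round(fraction * batch.size)
    if k == 0:
        return out
    rows = rng.choice(batch.size, size=k, replace=False)
    out.seq_zeroed[rows] = True
    for i in rows:
        real = out.pad_mask[i]
        out.codon_labels[i, real] = out.codon_ids[i, real]
    return out


def apply_token_masking(
    batch: Batch,
    codon_rate: float,
    aa_rate: float,
    rng: np.random.Generator,
) -> Batch:
    """Independently mask non-PAD tokens of non-hidden rows at each
    stream's rate; masked positions receive the MASK id and carry the
    original id as label.  PAD positions are never masked."""
    if not (0.0 <= codon_rate < 1.0 and 0.0 <= aa_rate < 1.0):
        raise ConfigError("mask rates must lie in [0, 1)")
    out = batch.copy()
    eligible = out.pad_mask & ~out.seq_zeroed[:, None]
    cod_hits = eligible & (rng.random(out.codon_ids.shape) < codon_rate)
    aa_hits = eligible & (rng.random(out.aa_ids.shape) < aa_rate)
    out.codon_labels[cod_hits] = out.codon_ids[cod_hits]
    out.codon_ids[cod_hits] = MASK_ID
    out.aa_labels[aa_hits] = out.aa_ids[aa_hits]
    out.aa_ids[aa_hits] = MASK_ID
    return out


def loss_and_grads(output: ModelOutput, batch: Batch) -> tuple[float, np.ndarray, np.ndarray, dict]:
    """Equally weighted mean cross-entropies of the two heads over their
    labelled positions.  Returns (loss, dcodon_logits, daa_logits, stats)."""
    c_loss, c_n, dc = nn.softmax_cross_entropy(output.codon_logits, batch.codon_labels, IGNORE_INDEX)
    a_loss, a_n, da = nn.softmax_cross_entropy(output.aa_logits, batch.aa_labels, IGNORE_INDEX)
    if c_n == 0 and a_n == 0:
        raise CodonMlmError("batch contains no labelled position")
    stats = {"codon_loss": c_loss, "aa_loss": a_loss, "codon_n": c_n, "aa_n": a_n}
    lab = batch.codon_labels != IGNORE_INDEX
    if c_n:
        pred = output.codon_logits[lab].argmax(axis=-1)
        stats["codon_correct"] = int((pred == batch.codon_labels[lab]).sum())
    else:
        stats["codon_correct"] = 0
    return c_loss + a_loss, dc, da, stats


def loss(output: ModelOutput, batch: Batch) -> float:
    """The scalar masked-LM objective (sum of the two head losses)."""
    return loss_and_grads(output, batch)[0]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 25
    batch_size: int = 16
    learning_rate: float = 1e-3
    codon_mask_rate: float = 0.15
    aa_mask_rate: float = 0.15
    schedule: CurriculumSchedule = field(default_factory=CurriculumSchedule)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.codon_mask_rate < 1.0 and 0.0 <= self.aa_mask_rate < 1.0):
            raise ConfigError("mask rates must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")

    @classmethod
    def compressed(cls, epochs: int = 25, seed: int = 0) -> "TrainConfig":
        """Desk-scale preset: compressed curriculum with a batch size and
        learning rate sized so a tiny model converges within tens of
        epochs on corpora of a few hundred short sequences."""
        return cls(
            epochs=epochs,
            batch_size=8,
            learning_rate=3e-3,
            schedule=CurriculumSchedule.compressed(),
            seed=seed,
        )


def _epoch_rng(seed: int, epoch: int) -> np.random.Generator:
    # forked per epoch so curriculum randomness survives resumption
    return np.random.default_rng([seed, epoch])


def fit(
    network: DualStreamEncoder,
    corpus: Sequence[TranscriptRecord],
    config: TrainConfig,
    start_epoch: int = 1,
    optimizer: Optional[nn.Adam] = None,
) -> tuple[DualStreamEncoder, pd.DataFrame, nn.Adam]:
    """Run the training loop; returns the trained network, a per-epoch
    history frame (loss, hidden fraction, masked-token accuracy) and the
    optimizer (for resumption)."""
    if not corpus:
        raise CodonMlmError("empty training corpus")
    if optimizer is None:
        optimizer = nn.Adam(network.params(), lr=config.learning_rate)
    history = []
    n = len(corpus)
    for epoch in range(start_epoch, config.epochs + 1):
        rng = _epoch_rng(config.seed, epoch)
        order = rng.permutation(n)
        fraction = sequence_mask_fraction(epoch, config.schedule)
        tot_loss = 0.0
        n_batches = 0
        labelled = 0
        correct = 0
        for lo in range(0, n, config.batch_size):
            rows = [corpus[i] for i in order[lo : lo + config.batch_size]]
            batch = make_batch(rows, network.config.max_len)
            batch = apply_sequence_zeroing(batch, fraction, rng)
            batch = apply_token_masking(
                batch, config.codon_mask_rate, config.aa_mask_rate, rng
            )
            out = network.forward(batch, train=True, rng=rng)
            try:
                value, dc, da, stats = loss_and_grads(out, batch)
            except CodonMlmError:
                continue  # a batch may have no labelled position at fraction 0
            if not np.isfinite(value):
                raise CodonMlmError(
                    f"non-finite loss {value} at epoch {epoch}; "
                    "lower the learning rate or check the corpus"
                )
            optimizer.zero_grad()
            network.backward(dc, da)
            optimizer.step()
            tot_loss += value
            n_batches += 1
            labelled += stats["codon_n"]
            correct += stats["codon_correct"]
        history.append(
            {
                "epoch": epoch,
                "loss": tot_loss / max(n_batches, 1),
                "hidden_fraction": fraction,
                "masked_codon_accuracy": correct / labelled if labelled else float("nan"),
            }
        )
    return network, pd.DataFrame(history), optimizer


# ---------------------------------------------------------------------------
# Model / Results presentation
# ---------------------------------------------------------------------------


class CodonModel:
    """A codon-optimization model specification bound to a training corpus.

    Mirrors the model/results idiom of statistical modelling packages:
    construct from data plus configuration, call :meth:`fit`, and work with
    the returned :class:`CodonModelResults`.
    """

    def __init__(
        self,
        corpus: Sequence[TranscriptRecord],
        model_config: Optional[ModelConfig] = None,
        train_config: Optional[TrainConfig] = None,
        seed: int = 0,
    ) -> None:
        if not corpus:
            raise CodonMlmError("empty training corpus")
        longest = max(len(r.protein) for r in corpus)
        self.model_config = model_config or ModelConfig.tiny(max_len=max(longest, 8))
        if self.model_config.max_len < longest:
            raise ConfigError(
                f"max_len {self.model_config.max_len} < longest sequence {longest}"
            )
        self.train_config = train_config or TrainConfig(seed=seed)
        self.corpus = list(corpus)
        self.seed = seed

    @classmethod
    def from_fasta(cls, cds_fasta: str | Path, **kwargs) -> "CodonModel":
        from .datasets import load_corpus

        return cls(load_corpus(cds_fasta), **kwargs)

    def fit(self) -> "CodonModelResults":
        network = DualStreamEncoder(self.model_config, seed=self.seed)
        network, history, optimizer = fit(network, self.corpus, self.train_config)
        return CodonModelResults(self, network, history, optimizer)


class CodonModelResults:
    """Fitted model: trained network plus training history and the
    evaluation / decoding surface."""

    def __init__(
        self,
        model: CodonModel,
        network: DualStreamEncoder,
        history: pd.DataFrame,
        optimizer: Optional[nn.Adam] = None,
    ) -> None:
        self.model = model
        self.network = network
        self.history = history
        self._optimizer = optimizer

    @property
    def n_parameters(self) -> int:
        return self.network.n_parameters()

    def predict(self, protein, constrain: bool = False):
        from .evalkit import predict_codons

        return predict_codons(self.network, protein, constrain=constrain)

    def evaluate(self, test_records, table=None, mfe_provider=None, constrain=False):
        from .evalkit import evaluate
        from .seqcore import CodonUsageTable

        if table is None:
            table = CodonUsageTable.from_corpus([r.cds for r in self.model.corpus])
        return evaluate(
            self.network,
            test_records,
            train_records=self.model.corpus,
            table=table,
            mfe_provider=mfe_provider,
            constrain=constrain,
        )

    def summary(self) -> str:
        h = self.history
        cfg = self.model.model_config
        tc = self.model.train_config
        lines = [
            "Dual-stream masked-LM codon model",
            "=" * 48,
            f"parameters:        {self.n_parameters:,}",
            f"embed/blocks/heads: {cfg.embed_dim}/{cfg.n_blocks}/{cfg.n_heads}",
            f"training sequences: {len(self.model.corpus)}",
            f"epochs:            {len(h)} (of {tc.epochs})",
            f"final loss:        {h['loss'].iloc[-1]:.4f}",
            f"final hidden frac: {h['hidden_fraction'].iloc[-1]:.2f}",
            f"final masked acc:  {h['masked_codon_accuracy'].iloc[-1]:.4f}",
        ]
        return "\n".join(lines)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        self.network.save(d)
        self.history.to_csv(d / "history.csv", index=False)
        if self._optimizer is not None:
            state = self._optimizer.state_dict()
            np.savez(
                d / "optimizer.npz",
                t=state["t"],
                **{f"m{i}": m for i, m in enumerate(state["m"])},
                **{f"v{i}": v for i, v in enumerate(state["v"])},
            )
        cfg = dataclasses.asdict(self.model.train_config)
        cfg["schedule"] = dataclasses.asdict(self.model.train_config.schedule)
        pd.Series(cfg, dtype=object).to_json(d / "train_config.json")
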