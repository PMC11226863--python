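"""The hiding curriculum, token masking, the masked-LM objective, and the
training loop's reproducibility."""

import math

import numpy as np
import pytest

from codonmlm import SyntheticSpec, generate_synthetic_corpus
from codonmlm.errors import CodonMlmError, ConfigError
from codonmlm.model import (
    AA_VOCAB,
    CODON_VOCAB,
    IGNORE_INDEX,
    MASK_ID,
    DualStreamEncoder,
    ModelConfig,
    ModelOutput,
    make_batch,
)
from codonmlm.training import (
    CodonModel,
    CurriculumSchedule,
    TrainConfig,
    apply_sequence_zeroing,
    apply_token_masking,
    fit,
    loss,
    sequence_mask_fraction,
)


class TestSchedule:
    @pytest.mark.parametrize(
        "epoch,expected",
        [(1, 0.0), (10, 0.0), (15, 0.0), (16, 0.05), (30, 0.05), (31, 0.10),
         (300, 0.95), (301, 1.0), (1000, 1.0)],
    )
    def test_default_constants(self, epoch, expected):
        assert sequence_mask_fraction(epoch, CurriculumSchedule()) == pytest.approx(expected)

    def test_monotone_nondecreasing_over_thousand_epochs(self):
        s = CurriculumSchedule()
        vals = [sequence_mask_fraction(e, s) for e in range(1, 1001)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[0] == 0.0 and vals[-1] == 1.0

    def test_compressed_schedule_shape(self):
        s = CurriculumSchedule.compressed()
        vals = [sequence_mask_fraction(e, s) for e in range(1, 31)]
        assert vals[0] == 0.0
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert sequence_mask_fraction(6, s) == 1.0
        assert all(v == 1.0 for v in vals[6:])

    def test_epoch_below_one_rejected(self):
        with pytest.raises(ConfigError):
            sequence_mask_fraction(0, CurriculumSchedule())

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ConfigError):
            CurriculumSchedule(warmup_epochs=10, full_mask_epoch=5)


@pytest.fixture()
def batch(micro_config):
    recs = generate_synthetic_corpus(SyntheticSpec(8, (6, 10), seed=1))
    return make_batch(recs, micro_config.max_len)


class TestSequenceZeroing:
    def test_fraction_zero_noop(self, batch):
        out = apply_sequence_zeroing(batch, 0.0, np.random.default_rng(0))
        assert not out.seq_zeroed.any()
        assert (out.codon_labels == IGNORE_INDEX).all()

    def test_fraction_one_labels_every_real_position(self, batch):
        out = apply_sequence_zeroing(batch, 1.0, np.random.default_rng(0))
        assert out.seq_zeroed.all()
        assert (out.codon_labels[out.pad_mask] == out.codon_ids[out.pad_mask]).all()
        assert (out.codon_labels[~out.pad_mask] == IGNORE_INDEX).all()

    def test_half_is_seeded_and_exact(self, batch):
        a = apply_sequence_zeroing(batch, 0.5, np.random.default_rng(7))
        b = apply_sequence_zeroing(batch, 0.5, np.random.default_rng(7))
        assert a.seq_zeroed.sum() == 4
        assert np.array_equal(a.seq_zeroed, b.seq_zeroed)


class TestTokenMasking:
    def test_rate_zero_sets_no_labels(self, batch):
        out = apply_token_masking(batch, 0.0, 0.0, np.random.default_rng(0))
        assert (out.codon_labels == IGNORE_INDEX).all()
        assert (out.aa_labels == IGNORE_INDEX).all()

    def test_masking_never_hits_pad(self, batch):
        out = apply_token_masking(batch, 0.5, 0.5, np.random.default_rng(0))
        assert (out.codon_ids[~out.pad_mask] != MASK_ID).all()
        assert (out.aa_labels[~out.pad_mask] == IGNORE_INDEX).all()

    def test_masked_positions_carry_original_label(self, batch):
        out = apply_token_masking(batch, 0.4, 0.0, np.random.default_rng(3))
        hit = out.codon_ids == MASK_ID
        assert (out.codon_labels[hit] == batch.codon_ids[hit]).all()
        assert (out.codon_labels[~hit] == IGNORE_INDEX).all()

    def test_zeroed_rows_excluded(self, batch):
        z = apply_sequence_zeroing(batch, 0.5, np.random.default_rng(1))
        out = apply_token_masking(z, 0.9, 0.9, np.random.default_rng(2))
        zeroed = out.seq_zeroed
        assert (out.aa_ids[zeroed] != MASK_ID).all()

    def test_binomial_rate(self):
        """Empirical masked fraction within 3 sd of the rate at 1e4
        positions."""
        recs = generate_synthetic_corpus(SyntheticSpec(200, (50, 50), seed=4))
        b = make_batch(recs)
        rate = 0.15
        out = apply_token_masking(b, rate, 0.0, np.random.default_rng(5))
        n = int(b.pad_mask.sum())
        hits = int((out.codon_ids == MASK_ID).sum())
        sd = math.sqrt(n * rate * (1 - rate))
        assert abs(hits - n * rate) < 3 * sd


class TestLoss:
    def test_uniform_logits_closed_form(self, batch):
        z = apply_sequence_zeroing(batch, 1.0, np.random.default_rng(0))
        out = ModelOutput(
            codon_logits=np.zeros((*z.codon_ids.shape, CODON_VOCAB)),
            aa_logits=np.zeros((*z.aa_ids.shape, AA_VOCAB)),
        )
        assert loss(out, z) == pytest.approx(math.log(CODON_VOCAB))

    def test_perfect_one_hot_logits_vanish(self, batch):
        z = apply_sequence_zeroing(batch, 1.0, np.random.default_rng(0))
        logits = np.zeros((*z.codon_ids.shape, CODON_VOCAB))
        lab = z.codon_labels != IGNORE_INDEX
        logits[lab] = -1e3
        idx = np.where(lab)
        logits[idx[0], idx[1], z.codon_labels[lab]] = 1e3
        out = ModelOutput(codon_logits=logits, aa_logits=np.zeros((*z.aa_ids.shape, AA_VOCAB)))
        assert loss(out, z) == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_batch_same_mean_loss(self, batch):
        z = apply_sequence_zeroing(batch, 1.0, np.random.default_rng(0))
        rng = np.random.default_rng(9)
        logits = rng.normal(size=(*z.codon_ids.shape, CODON_VOCAB))
        out = ModelOutput(codon_logits=logits, aa_logits=np.zeros((*z.aa_ids.shape, AA_VOCAB)))
        single = loss(out, z)
        z2 = z.copy()
        for name in ("aa_ids", "codon_ids", "pad_mask", "codon_labels", "aa_labels"):
            setattr(z2, name, np.concatenate([getattr(z, name)] * 2))
        z2.seq_zeroed = np.concatenate([z.seq_zeroed] * 2)
        out2 = ModelOutput(
            codon_logits=np.concatenate([logits] * 2),
            aa_logits=np.zeros((*z2.aa_ids.shape, AA_VOCAB)),
        )
        assert loss(out2, z2) == pytest.approx(single, abs=1e-12)

    def test_no_labels_raises(self, batch):
        out = ModelOutput(
            codon_logits=np.zeros((*batch.codon_ids.shape, CODON_VOCAB)),
            aa_logits=np.zeros((*batch.aa_ids.shape, AA_VOCAB)),
        )
        with pytest.raises(CodonMlmError):
            loss(out, batch)


@pytest.fixture(scope="module")
def tiny_run():
    corpus = generate_synthetic_corpus(SyntheticSpec(10, (5, 8), seed=5))
    cfg = ModelConfig(embed_dim=16, n_blocks=1, n_heads=2, ff_dim=32, max_len=12)
    tc = TrainConfig(
        epochs=12, batch_size=4, learning_rate=3e-3,
        schedule=CurriculumSchedule.compressed(), seed=1,
    )
    net = DualStreamEncoder(cfg, seed=1)
    return fit(net, corpus, tc), corpus, cfg, tc


class TestFit:
    def test_overfit_loss_decreases(self, tiny_run):
        (_, history, _), *_ = tiny_run
        assert history["loss"].iloc[-1] < history["loss"].iloc[0]

    def test_history_one_row_per_epoch(self, tiny_run):
        (_, history, _), _, _, tc = tiny_run
        assert list(history["epoch"]) == list(range(1, tc.epochs + 1))
        assert history["hidden_fraction"].iloc[-1] == 1.0

    def test_same_seed_bitwise_identical(self, tiny_run):
        (_, h1, _), corpus, cfg, tc = tiny_run
        net = DualStreamEncoder(cfg, seed=1)
        _, h2, _ = fit(net, corpus, tc)
        assert h1.equals(h2)

    def test_resumption_matches_straight_run(self, tiny_run):
        (_, h_full, _), corpus, cfg, tc = tiny_run
        import dataclasses

        net = DualStreamEncoder(cfg, seed=1)
        half = dataclasses.replace(tc, epochs=6)
        net, h_a, opt = fit(net, corpus, half)
        net, h_b, _ = fit(net, corpus, tc, start_epoch=7, optimizer=opt)
        import pandas as pd

        h_resumed = pd.concat([h_a, h_b], ignore_index=True)
        assert h_resumed.equals(h_full)

    def test_model_results_surface(self, tiny_run):
        _, corpus, cfg, tc = tiny_run
        results = CodonModel(corpus, model_config=cfg, train_config=tc, seed=1).fit()
        s = results.summary()
        assert "parameters" in s and "final loss" in s
        pred = results.predict(corpus[0].protein, constrain=True)
        from codonmlm import translate

        assert translate(pred).seq == corpus[0].protein.seq
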