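"""Canned desk-scale experiments.

These fix the study conditions used by the test battery and the
reproduction script: corpus sizes, sequence lengths, curriculum, and model
preset.  Each experiment derives all of its randomness from a single seed.
"""

from __future__ import annotations

import numpy as np

from .datasets import SyntheticSpec, generate_synthetic_corpus, random_usage_table
from .evalkit import EvalReport
from .seqcore import ProteinSeq, compute_cai, jcat_optimize
from .training import CodonModel, TrainConfig


def jcat_cai_identity(seed: int, n_proteins: int = 100, n_tables: int = 10) -> list[float]:
    """CAI of one-codon optimized sequences against their optimizing
    tables: ``n_proteins`` random proteins scored under ``n_tables``
    random usage tables (each protein paired with one of the tables in
    round-robin).  Every value is exactly 1 when optimizer and index
    agree."""
    rng = np.random.default_rng([seed, 1])
    tables = [random_usage_table(rng) for _ in range(n_tables)]
    from .seqcore import AMINO_ACIDS

    values = []
    for i in range(n_proteins):
        length = int(rng.integers(10, 80))
        protein = ProteinSeq("".join(rng.choice(list(AMINO_ACIDS), size=length)))
        table = tables[i % n_tables]
        values.append(compute_cai(jcat_optimize(protein, table), table))
    return values


def deterministic_rule_experiment(seed: int) -> EvalReport:
    """The scaled-down accuracy study: 500 training and 100 held-out
    sequences (30-60 codons) whose synonymous choice is a fixed function
    of the previous residue; tiny model preset, compressed curriculum
    (full hiding by epoch 6), 25 epochs; decode the held-out proteins
    with the codon stream hidden and score per-sequence codon accuracy."""
    train = generate_synthetic_corpus(
        SyntheticSpec(500, (30, 60), deterministic_rule=True, seed=abs(seed * 100 + 11) % 2**31)
    )
    test = generate_synthetic_corpus(
        SyntheticSpec(100, (30, 60), deterministic_rule=True, seed=abs(seed * 100 + 12) % 2**31)
    )
    results = CodonModel(
        train, train_config=TrainConfig.compressed(epochs=25, seed=seed), seed=seed
    ).fit()
    return results.evaluate(test)


def usage_recovery_experiment(seed: int, epochs: int = 40) -> EvalReport:
    """The planted-bias recovery study: a strongly biased planted usage
    table with first-order dependence (pair_dependence 0.5); 500 training
    and 100 held-out sequences; tiny preset under the compressed
    curriculum; report usage and bicodon correlations between the decoded
    set and the training corpus."""
    rng = np.random.default_rng(abs(seed * 100 + 7) % 2**31)
    table = random_usage_table(rng)
    train = generate_synthetic_corpus(
        SyntheticSpec(500, (30, 60), planted_usage=table, pair_dependence=0.5,
                      seed=abs(seed * 100 + 21) % 2**31)
    )
    test = generate_synthetic_corpus(
        SyntheticSpec(100, (30, 60), planted_usage=table, pair_dependence=0.5,
                      seed=abs(seed * 100 + 22) % 2**31)
    )
    results = CodonModel(
        train, train_config=TrainConfig.compressed(epochs=epochs, seed=seed), seed=seed
    ).fit()
    return results.evaluate(test)
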