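"""Protein-only codon decoding and the evaluation battery: per-sequence
codon accuracy (summarised by the median), CAI against a usage table,
codon and bicodon usage frequency vectors, their Pearson correlations with
the training corpus, and an optional minimum-free-energy adapter.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .datasets import TranscriptRecord
from .errors import (
    ConfigError,
    EmptyCorpusError,
    LengthMismatchError,
    MfeProviderUnavailableError,
    ZeroVarianceError,
)
from .model import CODON_TO_ID, DualStreamEncoder, make_batch
from .seqcore import (
    CODON_INDEX,
    CODONS,
    STANDARD_CODE,
    Cds,
    CodonUsageTable,
    ProteinSeq,
    compute_cai,
)

NEG = -1e30


def predict_codons(
    network: DualStreamEncoder, protein: ProteinSeq, constrain: bool = False
) -> Cds:
    """Decode a codon sequence from protein alone: one forward pass with
    the codon stream fully hidden, then position-wise argmax over codon
    logits.

    With ``constrain=True`` codons outside each position's synonymous
    family are excluded before the argmax, so the decoded sequence is
    guaranteed to translate back to ``protein`` for any model.
    """
    if len(protein) > network.config.max_len:
        raise ConfigError(
            f"protein length {len(protein)} exceeds max_len {network.config.max_len}"
        )
    record = _protein_only_record(protein)
    batch = make_batch([record], network.config.max_len)
    batch.seq_zeroed[:] = True
    out = network.forward(batch, train=False)
    logits = out.codon_logits[0]  # (L, codon_vocab)
    L = len(protein)
    if constrain:
        masked = np.full_like(logits, NEG)
        for i, aa in enumerate(protein.seq):
            for c in STANDARD_CODE.families[aa]:
                masked[i, CODON_TO_ID[c]] = logits[i, CODON_TO_ID[c]]
        logits = masked
    else:
        # PAD and MASK ids are never valid decodes
        logits = logits.copy()
        logits[:, :2] = NEG
    ids = logits[:L].argmax(axis=-1)
    codons = [CODONS[i - 2] for i in ids]
    return Cds("".join(codons))


def _protein_only_record(protein: ProteinSeq) -> TranscriptRecord:
    # placeholder CDS (any translation-consistent filler); the codon stream
    # is zeroed before the network ever sees it
    filler = "".join(STANDARD_CODE.families[aa][0] for aa in protein.seq)
    return TranscriptRecord(id="query", cds=Cds(filler), protein=protein)


def codon_accuracy(pred: Cds, ref: Cds) -> float:
    """Fraction of aligned positions carrying the identical codon."""
    p, r = pred.coding_codons, ref.coding_codons
    if len(p) != len(r):
        raise LengthMismatchError(f"codon counts differ: {len(p)} vs {len(r)}")
    return sum(a == b for a, b in zip(p, r)) / len(p)


def usage_frequencies(cds_list: Sequence[Cds]) -> np.ndarray:
    """Pooled codon frequencies over all sequences, in lexicographic codon
    order, normalised to sum 1."""
    if not cds_list:
        raise EmptyCorpusError("cannot compute usage of an empty list")
    counts = np.zeros(64)
    for cds in cds_list:
        for c in cds.coding_codons:
            counts[CODON_INDEX[c]] += 1
    return counts / counts.sum()


def pair_usage_frequencies(cds_list: Sequence[Cds]) -> np.ndarray:
    """Frequencies of ordered adjacent codon pairs (bicodons) within each
    sequence — no cross-sequence pairs — as a 4096-vector in lexicographic
    (first, second) order, normalised to sum 1."""
    if not cds_list:
        raise EmptyCorpusError("cannot compute pair usage of an empty list")
    counts = np.zeros(64 * 64)
    for cds in cds_list:
        cods = cds.coding_codons
        if len(cods) < 2:
            raise ConfigError("pair usage needs sequences of at least 2 codons")
        for a, b in zip(cods, cods[1:]):
            counts[CODON_INDEX[a] * 64 + CODON_INDEX[b]] += 1
    return counts / counts.sum()


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise LengthMismatchError("inputs must be equal-length 1-d vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# MFE adapter
# ---------------------------------------------------------------------------


class RnaFoldProvider:
    """Minimum free energy via an external ``RNAfold`` executable.

    Availability is detectable up front; never silently returns zero.
    """

    def __init__(self, executable: str = "RNAfold") -> None:
        self.executable = executable

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def __call__(self, cds: Cds) -> float:
        if not self.available():
            raise MfeProviderUnavailableError(f"{self.executable} not on PATH")
        proc = subprocess.run(
            [self.executable, "--noPS"],
            input=cds.seq + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        # last line: "....structure.... (-12.30)"
        tail = proc.stdout.strip().splitlines()[-1]
        return float(tail[tail.rindex("(") + 1 : tail.rindex(")")])


# ---------------------------------------------------------------------------
# End-to-end evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    per_seq_accuracy: list[float]
    median_accuracy: float
    aa_fidelity: list[float]
    cai_values: list[float]
    usage_pred: np.ndarray
    usage_ref: np.ndarray
    pair_usage_pred: np.ndarray
    pair_usage_ref: np.ndarray
    pcc_usage: float
    pcc_pair: float
    mfe_values: Optional[list[float]] = None
    mfe_errors: Optional[dict[str, str]] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("usage_pred", "usage_ref", "pair_usage_pred", "pair_usage_ref"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def usage_scatter(self) -> list[tuple[str, float, float]]:
        """(codon, predicted frequency, training frequency) rows for the
        usage-correlation scatter."""
        return [
            (c, float(self.usage_pred[i]), float(self.usage_ref[i]))
            for i, c in enumerate(CODONS)
        ]


def evaluate(
    network: DualStreamEncoder,
    test_records: Sequence[TranscriptRecord],
    train_records: Sequence[TranscriptRecord],
    table: CodonUsageTable,
    mfe_provider: Optional[Callable[[Cds], float]] = None,
    constrain: bool = False,
) -> EvalReport:
    """Decode every test protein and score the decoded set.

    Accuracy is computed per sequence against its reference CDS and
    summarised by the median; usage and bicodon vectors of the decoded set
    are correlated (Pearson) against the training corpus; CAI is scored
    per decoded sequence against ``table``.  Amino-acid fidelity (fraction
    of decoded codons translating to the intended residue) is reported
    alongside, since unconstrained decoding may leave a family.
    """
    if not test_records:
        raise EmptyCorpusError("empty test set")
    decoded: list[Cds] = []
    accs: list[float] = []
    fidelity: list[float] = []
    for rec in test_records:
        pred = predict_codons(network, rec.protein, constrain=constrain)
        decoded.append(pred)
        accs.append(codon_accuracy(pred, rec.cds))
        ok = sum(
            STANDARD_CODE.codon_to_aa[c] == aa
            for c, aa in zip(pred.coding_codons, rec.protein.seq)
        )
        fidelity.append(ok / len(rec.protein))
    usage_pred = usage_frequencies(decoded)
    usage_ref = usage_frequencies([r.cds for r in train_records])
    pair_pred = pair_usage_frequencies(decoded)
    pair_ref = pair_usage_frequencies([r.cds for r in train_records])
    mfe_values = None
    mfe_errors: dict[str, str] = {}
    if mfe_provider is not None:
        mfe_values = []
        for rec, cds in zip(test_records, decoded):
            try:
                mfe_values.append(mfe_provider(cds))
            except Exception as exc:  # per-sequence, never fatal
                mfe_values.append(float("nan"))
                mfe_errors[rec.id] = str(exc)
    return EvalReport(
        per_seq_accuracy=accs,
        median_accuracy=float(np.median(accs)),
        aa_fidelity=fidelity,
        cai_values=[compute_cai(c, table) for c in decoded],
        usage_pred=usage_pred,
        usage_ref=usage_ref,
        pair_usage_pred=pair_pred,
        pair_usage_ref=pair_ref,
        pcc_usage=pearson_corr(usage_pred, usage_ref),
        pcc_pair=pearson_corr(pair_pred, pair_ref),
        mfe_values=mfe_values,
        mfe_errors=mfe_errors or None,
    )
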