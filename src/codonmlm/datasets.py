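"""Corpus construction: expression filtering, CAI/MFE filtering, admixture
of one-amino-acid-one-codon optimized sequences, and the synthetic-corpus
generator used for all desk-scale experiments.

The synthetic generator emulates a corpus of highly expressed coding
sequences: synonymous-codon choice follows a *planted* per-family
categorical distribution, optionally blended with a first-order
previous-codon preference (a tilt toward codons whose first base repeats
the previous codon's third base, a simple stand-in for bicodon bias), or
replaced by a fixed deterministic rule of the previous amino acid.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import (
    ConfigError,
    EmptyCorpusError,
    MfeProviderUnavailableError,
    MissingTpmError,
)
from .seqcore import (
    AMINO_ACIDS,
    CODONS,
    STANDARD_CODE,
    Cds,
    CodonUsageTable,
    GeneticCode,
    ProteinSeq,
    compute_cai,
    jcat_optimize,
    read_fasta,
    translate,
    write_fasta,
)

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: concentration of the per-family Dirichlet used for planted usage tables;
#: 0.1 gives strongly biased families (modal codon ~0.8 of family mass),
#: the regime characteristic of highly expressed transcripts
PLANTED_DIRICHLET_ALPHA = 0.1

#: strength of the previous-codon tilt in the pair-dependent channel
PAIR_TILT_KAPPA = 1.0


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript flowing through preprocessing: id, CDS, protein and
    an optional expression level (TPM)."""

    id: str
    cds: Cds
    protein: ProteinSeq
    tpm: Optional[float] = None

    def __post_init__(self) -> None:
        if translate(self.cds).seq != self.protein.seq:
            raise ConfigError(f"record {self.id}: CDS does not translate to protein")
        if self.tpm is not None and self.tpm < 0:
            raise ConfigError(f"record {self.id}: negative TPM")


@dataclass(frozen=True)
class DatasetSpec:
    """Preprocessing parameters.

    ``tpm_threshold`` keeps records with TPM strictly greater than the
    threshold.  ``jcat_proportion`` is the fraction of surviving records
    whose CDS is replaced by its one-codon optimized counterpart.
    """

    tpm_threshold: float = 5.0
    cai_min: Optional[float] = None
    mfe_max: Optional[float] = None
    jcat_proportion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.jcat_proportion <= 1.0:
            raise ConfigError("jcat_proportion must lie in [0, 1]")


#: shipped defaults for the admixture series; these are this package's
#: presets, not values taken from any external study
DEFAULT_JCAT_PROPORTIONS = (0.0, 0.1, 0.25, 0.5)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic corpus generator."""

    n_sequences: int
    length_range: tuple[int, int] = (30, 60)
    planted_usage: Optional[CodonUsageTable] = None  # default: seeded random table
    pair_dependence: float = 0.0
    deterministic_rule: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ConfigError(f"degenerate length_range {self.length_range}")
        if self.n_sequences < 1:
            raise ConfigError("n_sequences must be >= 1")
        if not 0.0 <= self.pair_dependence <= 1.0:
            raise ConfigError("pair_dependence must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Filters and admixture
# ---------------------------------------------------------------------------


def filter_by_tpm(
    records: Sequence[TranscriptRecord], threshold: float
) -> list[TranscriptRecord]:
    """Keep records with TPM strictly greater than ``threshold``."""
    kept = []
    for r in records:
        if r.tpm is None:
            raise MissingTpmError(f"record {r.id} has no TPM but a TPM filter is active")
        if r.tpm > threshold:
            kept.append(r)
    return kept


def filter_by_cai_mfe(
    records: Sequence[TranscriptRecord],
    table: CodonUsageTable,
    cai_min: Optional[float] = None,
    mfe_max: Optional[float] = None,
    mfe_provider: Optional[Callable[[Cds], float]] = None,
) -> list[TranscriptRecord]:
    """Keep records with CAI >= cai_min and MFE <= mfe_max.

    An absent bound imposes no constraint.  Requesting an MFE bound
    without a folding backend is an error, never a silent pass.
    """
    if mfe_max is not None and mfe_provider is None:
        raise MfeProviderUnavailableError("mfe_max set but no MFE provider available")
    kept = []
    for r in records:
        if cai_min is not None and compute_cai(r.cds, table) < cai_min:
            continue
        if mfe_max is not None and mfe_provider(r.cds) > mfe_max:
            continue
        kept.append(r)
    return kept


def mix_jcat(
    records: Sequence[TranscriptRecord],
    proportion: float,
    table: CodonUsageTable,
    seed: int = 0,
) -> list[TranscriptRecord]:
    """Replace the CDS of a uniformly sampled round(proportion * n) subset
    of records with its one-codon optimized counterpart; proteins are
    untouched, order is preserved, the sample is seeded-reproducible."""
    if not 0.0 <= proportion <= 1.0:
        raise ConfigError("proportion must lie in [0, 1]")
    n = len(records)
    k = round(proportion * n)
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=k, replace=False).tolist()) if k else set()
    out = []
    for i, r in enumerate(records):
        if i in chosen:
            out.append(
                TranscriptRecord(
                    id=r.id,
                    cds=jcat_optimize(r.protein, table),
                    protein=r.protein,
                    tpm=r.tpm,
                )
            )
        else:
            out.append(r)
    return out


def train_test_split(
    records: Sequence[TranscriptRecord], test_fraction: float, seed: int = 0
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Disjoint, exhaustive, seeded partition into (train, test)."""
    if not 0.0 < test_fraction < 1.0:
        raise ConfigError("test_fraction must lie strictly between 0 and 1")
    if len(records) < 2:
        raise EmptyCorpusError("need at least 2 records to split")
    n = len(records)
    n_test = max(1, round(test_fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test


# ---------------------------------------------------------------------------
# Synthetic corpus
# ---------------------------------------------------------------------------


def random_usage_table(
    rng: np.random.Generator,
    alpha: float = PLANTED_DIRICHLET_ALPHA,
    code: GeneticCode = STANDARD_CODE,
) -> CodonUsageTable:
    """Draw a planted usage table: per family a Dirichlet(alpha) split of
    the family mass, families weighted equally."""
    counts: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        fam = code.families[aa]
        probs = rng.dirichlet([alpha] * len(fam)) if len(fam) > 1 else np.array([1.0])
        for c, p in zip(fam, probs):
            # scale into pseudo-counts well above the zero floor
            counts[c] = 1000.0 * float(p) + 1.0
    return CodonUsageTable.from_counts(counts, code=code)


def deterministic_codon_rule(
    prev_aa: Optional[str], aa: str, code: GeneticCode = STANDARD_CODE
) -> str:
    """The fixed learnable rule: the synonymous choice for ``aa`` is indexed
    by the previous amino acid's alphabet rank (first position uses the
    lexicographically first codon)."""
    fam = code.families[aa]
    if prev_aa is None:
        return fam[0]
    return fam[AA_INDEX[prev_aa] % len(fam)]


def _family_dists(
    table: CodonUsageTable, code: GeneticCode
) -> dict[str, np.ndarray]:
    out = {}
    for aa in AMINO_ACIDS:
        fam = code.families[aa]
        p = np.array([table.freq[c] for c in fam], dtype=float)
        out[aa] = p / p.sum()
    return out


def _tilted_dist(
    base: np.ndarray, fam: tuple[str, ...], prev_codon: str, kappa: float
) -> np.ndarray:
    w = np.array(
        [np.exp(kappa) if c[0] == prev_codon[2] else 1.0 for c in fam], dtype=float
    )
    p = base * w
    return p / p.sum()


def generate_synthetic_corpus(spec: SyntheticSpec) -> list[TranscriptRecord]:
    """Generate records whose proteins are uniform over the 20 letters and
    whose synonymous-codon choices follow the planted distribution, blended
    with a previous-codon-conditioned tilt by ``pair_dependence`` — or, when
    ``deterministic_rule`` is set, a fixed function of the previous residue.

    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    code = STANDARD_CODE
    table = spec.planted_usage or random_usage_table(rng)
    fam_dists = _family_dists(table, code)
    lo, hi = spec.length_range
    aas = list(AMINO_ACIDS)
    records = []
    for i in range(spec.n_sequences):
        length = int(rng.integers(lo, hi + 1))
        protein = "".join(rng.choice(aas, size=length))
        codons: list[str] = []
        prev_codon: Optional[str] = None
        prev_aa: Optional[str] = None
        for aa in protein:
            fam = code.families[aa]
            if spec.deterministic_rule:
                codon = deterministic_codon_rule(prev_aa, aa, code)
            else:
                p = fam_dists[aa]
                if prev_codon is not None and rng.random() < spec.pair_dependence:
                    p = _tilted_dist(p, fam, prev_codon, PAIR_TILT_KAPPA)
                codon = fam[int(rng.choice(len(fam), p=p))]
            codons.append(codon)
            prev_codon, prev_aa = codon, aa
        records.append(
            TranscriptRecord(
                id=f"synth_{i:05d}",
                cds=Cds("".join(codons)),
                protein=ProteinSeq(protein),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Corpus I/O: paired FASTA files, TPM table, JSON manifest
# ---------------------------------------------------------------------------


def read_tpm_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV: transcript id, TPM.  Header and ``#`` lines skipped."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                out[parts[0]] = float(parts[1])
            except (IndexError, ValueError):
                if not out:  # tolerate a single header line
                    continue
                raise ConfigError(f"malformed TPM line: {line!r}")
    return out


def load_corpus(
    cds_fasta: str | Path,
    tpm_table: Optional[str | Path] = None,
) -> list[TranscriptRecord]:
    """Read a CDS FASTA (proteins derived by translation) and optionally
    attach TPM values by record id."""
    tpm = read_tpm_table(tpm_table) if tpm_table else {}
    records = []
    for rid, seq in read_fasta(cds_fasta):
        cds = Cds(seq)
        records.append(
            TranscriptRecord(
                id=rid, cds=cds, protein=translate(cds), tpm=tpm.get(rid)
            )
        )
    return records


def write_corpus(
    records: Sequence[TranscriptRecord],
    out_dir: str | Path,
    manifest_extra: Optional[dict] = None,
) -> None:
    """Write cds.fasta, protein.fasta and manifest.json to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([(r.id, r.cds.seq) for r in records], out / "cds.fasta")
    write_fasta([(r.id, r.protein.seq) for r in records], out / "protein.fasta")
    manifest = {"n_records": len(records)}
    if manifest_extra:
        manifest.update(manifest_extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def preprocess(
    records: Sequence[TranscriptRecord],
    spec: DatasetSpec,
    table: Optional[CodonUsageTable] = None,
    mfe_provider: Optional[Callable[[Cds], float]] = None,
) -> tuple[list[TranscriptRecord], dict]:
    """The full preprocessing pipeline: TPM filter, CAI/MFE filter, one-codon
    admixture.  Returns the surviving records and a manifest of per-stage
    kept/dropped counts.  The usage table for CAI and admixture defaults to
    one built from the TPM survivors themselves."""
    manifest: dict = {"input": len(records), "spec": dataclasses.asdict(spec)}
    kept = filter_by_tpm(records, spec.tpm_threshold)
    manifest["after_tpm"] = {"kept": len(kept), "dropped": len(records) - len(kept)}
    if not kept:
        raise EmptyCorpusError("no records survive the TPM filter")
    if table is None:
        table = CodonUsageTable.from_corpus([r.cds for r in kept])
    before = len(kept)
    kept = filter_by_cai_mfe(kept, table, spec.cai_min, spec.mfe_max, mfe_provider)
    manifest["after_cai_mfe"] = {"kept": len(kept), "dropped": before - len(kept)}
    mixed = mix_jcat(kept, spec.jcat_proportion, table, seed=spec.seed)
    manifest["jcat_replaced"] = round(spec.jcat_proportion * len(kept))
    return mixed, manifest
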