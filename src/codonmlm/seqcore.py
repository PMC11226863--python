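"""Genetic-code primitives, codon usage statistics, CAI, and the
"one amino acid — one codon" optimizer.

The codon adaptation index (CAI) of a coding sequence is the geometric mean
of per-codon relative adaptiveness values w, where w(c) is the frequency of
codon c divided by the frequency of the most-used codon in c's synonymous
family.  A sequence built exclusively from modal codons therefore has
CAI = 1 by construction.

Conventions (documented, fixed):

* standard genetic code (NCBI table 1) only; alternative codes may be passed
  as a ``GeneticCode`` instance but no table-id machinery exists;
* single-codon families participate in CAI (their w = 1 contributes to the
  length normalisation), stop codons never do;
* zero-count codons receive a pseudo-count of 0.5 before frequencies and w
  are computed, so CAI is always finite;
* ties in the optimizer break to the lexicographically smallest codon.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    CdsLengthError,
    EmptyCorpusError,
    InternalStopError,
    InvalidAminoAcidError,
    InvalidNucleotideError,
    StopOnlyCdsError,
)

BASES = "ACGT"
#: all 64 codons in lexicographic order — the canonical axis for every
#: usage vector in the package
CODONS: tuple[str, ...] = tuple("".join(p) for p in product(BASES, repeat=3))
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP_SYMBOL = "*"

#: pseudo-count applied to never-observed codons before w computation
ZERO_COUNT_FLOOR = 0.5


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map plus the synonymous-family index.

    ``families`` maps each amino-acid letter to its codons sorted
    lexicographically, which fixes a deterministic iteration order for
    tie-breaks and tokenization.
    """

    codon_to_aa: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]]
    stop_codons: frozenset[str]

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[1]
        codon_to_aa = {c: table.forward_table.get(c, STOP_SYMBOL) for c in CODONS}
        families = {
            aa: tuple(sorted(c for c in CODONS if codon_to_aa[c] == aa))
            for aa in AMINO_ACIDS
        }
        return cls(
            codon_to_aa=codon_to_aa,
            families=families,
            stop_codons=frozenset(table.stop_codons),
        )

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]


#: the standard genetic code, shared by default everywhere
STANDARD_CODE = GeneticCode.standard()


@dataclass(frozen=True)
class Cds:
    """A validated coding sequence: ACGT only, length a positive multiple
    of 3, any stop codon strictly terminal."""

    seq: str
    code: GeneticCode = field(default=STANDARD_CODE, repr=False, compare=False)

    def __post_init__(self) -> None:
        s = self.seq
        if len(s) == 0 or len(s) % 3 != 0:
            raise CdsLengthError(f"CDS length {len(s)} is not a positive multiple of 3")
        bad = set(s) - set(BASES)
        if bad:
            raise InvalidNucleotideError(f"non-ACGT characters in CDS: {sorted(bad)}")
        for i in range(0, len(s) - 3, 3):
            if s[i : i + 3] in self.code.stop_codons:
                raise InternalStopError(f"internal stop codon at nucleotide {i}")

    @property
    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    @property
    def coding_codons(self) -> list[str]:
        """Codons excluding a trailing stop, if present."""
        cods = self.codons
        if cods and cods[-1] in self.code.stop_codons:
            return cods[:-1]
        return cods

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinSeq:
    """A validated amino-acid sequence over the 20 standard letters."""

    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise InvalidAminoAcidError("empty protein sequence")
        bad = set(self.seq) - set(AMINO_ACIDS)
        if bad:
            raise InvalidAminoAcidError(f"non-standard amino-acid letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


def translate(cds: Cds, code: GeneticCode = STANDARD_CODE) -> ProteinSeq:
    """Translate a CDS; a trailing stop codon is stripped, never emitted."""
    aas = []
    for codon in cds.coding_codons:
        aas.append(code.codon_to_aa[codon])
    if not aas:
        raise StopOnlyCdsError("CDS consists only of a stop codon")
    return ProteinSeq("".join(aas))


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon frequencies plus derived relative adaptiveness.

    ``freq`` is normalised over all 64 codons (global frequencies);
    ``w`` is frequency divided by the within-family maximum, so each
    synonymous family's modal codon has w = 1 exactly.  ``w`` is always
    derived from ``freq`` — the two can never disagree.
    """

    freq: Mapping[str, float]
    w: Mapping[str, float]
    code: GeneticCode = field(default=STANDARD_CODE, repr=False, compare=False)

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, float], code: GeneticCode = STANDARD_CODE
    ) -> "CodonUsageTable":
        floored = {c: max(float(counts.get(c, 0.0)), ZERO_COUNT_FLOOR) for c in CODONS}
        total = sum(floored.values())
        freq = {c: floored[c] / total for c in CODONS}
        w: dict[str, float] = {}
        for aa in AMINO_ACIDS:
            fam = code.families[aa]
            fam_max = max(freq[c] for c in fam)
            for c in fam:
                w[c] = freq[c] / fam_max
        for c in code.stop_codons:
            w[c] = 1.0  # stops never scored; defined for completeness
        return cls(freq=freq, w=w, code=code)

    @classmethod
    def from_corpus(
        cls, corpus: Sequence[Cds], code: GeneticCode = STANDARD_CODE
    ) -> "CodonUsageTable":
        if not corpus:
            raise EmptyCorpusError("cannot build a usage table from an empty corpus")
        counts = {c: 0 for c in CODONS}
        for cds in corpus:
            for codon in cds.coding_codons:
                counts[codon] += 1
        return cls.from_counts(counts, code=code)

    def modal_codon(self, aa: str) -> str:
        """Most frequent codon of an amino acid's family; lexicographic
        tie-break via the sorted family order and strict > comparison."""
        fam = self.code.families[aa]
        best = fam[0]
        for c in fam[1:]:
            if self.freq[c] > self.freq[best]:
                best = c
        return best

    def write(self, path: str | Path) -> None:
        # counts per million, so the 0.5 pseudo-count floor on re-read is
        # negligible for every observed codon
        with open(path, "w") as fh:
            fh.write("codon\tcount\n")
            for c in CODONS:
                fh.write(f"{c}\t{self.freq[c] * 1e6:.6f}\n")

    @classmethod
    def read(cls, path: str | Path, code: GeneticCode = STANDARD_CODE) -> "CodonUsageTable":
        """Read a tab-separated codon,count table.  A header line and
        ``#`` comments are tolerated; counts may be raw or normalised."""
        counts: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0].upper() not in CODON_INDEX:
                    continue  # header or junk line
                counts[parts[0].upper()] = float(parts[1])
        if not counts:
            raise EmptyCorpusError(f"no codon rows found in {path}")
        return cls.from_counts(counts, code=code)


def build_usage_table(
    corpus: Sequence[Cds], code: GeneticCode = STANDARD_CODE
) -> CodonUsageTable:
    """Count codons over a corpus and derive frequencies and w."""
    return CodonUsageTable.from_corpus(corpus, code=code)


def compute_cai(cds: Cds, table: CodonUsageTable) -> float:
    """Geometric mean of w over the coding codons of ``cds``.

    Stop codons are excluded; single-codon families are included with
    w = 1.  Computed in log space for numerical robustness.
    """
    codons = cds.coding_codons
    if not codons:
        raise StopOnlyCdsError("cannot score a stop-only CDS")
    log_sum = sum(math.log(table.w[c]) for c in codons)
    return math.exp(log_sum / len(codons))


def jcat_optimize(
    protein: ProteinSeq,
    table: CodonUsageTable,
    code: GeneticCode = STANDARD_CODE,
) -> Cds:
    """One amino acid — one codon: substitute every residue with its
    family's most frequent codon in ``table``.

    The result translates back to ``protein`` and has CAI exactly 1
    against the same table.
    """
    if table.code is not code and table.code.families != code.families:
        raise InvalidAminoAcidError("usage table was built for a different genetic code")
    return Cds("".join(table.modal_codon(aa) for aa in protein.seq), code=code)


# ---------------------------------------------------------------------------
# FASTA I/O — thin wrappers over Biopython keeping (id, sequence) tuples
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise EmptyCorpusError(f"no FASTA records in {path}")
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        warnings.warn(f"duplicate record ids in {path}; keeping all", stacklevel=2)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
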