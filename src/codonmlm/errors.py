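"""Exception hierarchy.

Every malformed-input condition raises a distinct, named error so callers
(and the CLI exit-code mapping) can tell them apart.
"""


class CodonMlmError(Exception):
    """Base class for all package errors."""


class SequenceError(CodonMlmError, ValueError):
    """Base class for malformed biological sequences."""


class CdsLengthError(SequenceError):
    """CDS length is zero or not divisible by 3."""


class InvalidNucleotideError(SequenceError):
    """CDS contains a character outside ACGT."""


class InternalStopError(SequenceError):
    """A stop codon occurs before the final codon of a CDS."""


class StopOnlyCdsError(SequenceError):
    """CDS consists of nothing but a stop codon (no coding codon to score)."""


class InvalidAminoAcidError(SequenceError):
    """Protein contains a letter outside the 20 standard amino acids."""


class EmptyCorpusError(CodonMlmError, ValueError):
    """An operation that needs at least one sequence received none."""


class MissingTpmError(CodonMlmError, ValueError):
    """A TPM filter was requested but a record carries no TPM value."""


class MfeProviderUnavailableError(CodonMlmError, RuntimeError):
    """An MFE bound was requested but no folding backend is available."""


class LengthMismatchError(CodonMlmError, ValueError):
    """Two sequences that must align position-by-position have different lengths."""


class ZeroVarianceError(CodonMlmError, ValueError):
    """Pearson correlation of a constant vector is undefined."""


class ConfigError(CodonMlmError, ValueError):
    """Invalid model / training / dataset configuration."""
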