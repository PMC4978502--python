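"""Exception hierarchy for alignment scoring."""


class SpScoreError(Exception):
    """Base class for all package errors."""


class AlignmentFormatError(SpScoreError):
    """Structurally invalid alignment (unequal lengths, too few records, ...)."""


class AlphabetError(SpScoreError):
    """A sequence character falls outside the declared alphabet."""


class MatrixError(SpScoreError):
    """Invalid or incomplete substitution matrix."""


class ConfigError(SpScoreError):
    """Infeasible or inconsistent generator/run configuration."""


class UsageError(SpScoreError):
    """API misuse (e.g. scoring a pair of a sequence with itself)."""
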