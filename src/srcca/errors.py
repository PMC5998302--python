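"""Exception hierarchy.

Every failure mode the pipeline can signal deliberately derives from
:class:`SrccaError`, so callers (and the CLI) can distinguish anticipated
data problems from genuine bugs.
"""


class SrccaError(Exception):
    """Base class for all deliberate pipeline errors."""


class FormatError(SrccaError):
    """A file does not conform to its declared dialect (names the file)."""


class ValidationError(SrccaError):
    """A container invariant is violated (duplicate ids, negative values...)."""


class UsageError(SrccaError):
    """An operation was called with arguments outside its contract."""


class UnitError(UsageError):
    """An operation received a matrix in the wrong unit."""


class GeneLookupError(SrccaError):
    """A requested gene id is absent from the matrix."""

    def __init__(self, gene: str, candidates=()):
        self.gene = gene
        self.candidates = list(candidates)
        msg = f"gene {gene!r} not found in matrix"
        if self.candidates:
            msg += f"; closest ids: {', '.join(self.candidates)}"
        super().__init__(msg)


class DegenerateInputError(SrccaError):
    """A statistic is undefined on this input (e.g. constant target gene)."""


class EmptyResultError(SrccaError):
    """A filter removed everything; silence would hide a broken dataset."""


class ConfigError(SrccaError):
    """A panel / generator configuration is inconsistent."""
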