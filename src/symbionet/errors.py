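"""Exception hierarchy shared across the package."""


class SymbionetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SymbionetError, ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(SymbionetError, ValueError):
    """A record or matrix violates a domain invariant."""


class MissingLookupError(SymbionetError, KeyError):
    """A taxon has no entry in a required lookup table (strict mode)."""

    def __init__(self, kind: str, names):
        self.kind = kind
        self.names = sorted(set(names))
        super().__init__(f"no {kind} entry for: {', '.join(self.names)}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class EmptySelectionError(SymbionetError, ValueError):
    """A filter or threshold removed every row/record."""


class PipelineStageError(SymbionetError, RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
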