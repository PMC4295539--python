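"""Exception hierarchy for the pipeline engine."""


class PipelineError(Exception):
    """Base class for all engine errors."""


class SchemaError(PipelineError):
    """A declarative document (interface, tasklist, parameters) is malformed."""


class DomainError(PipelineError):
    """A module names a domain that is not a node of the domain tree."""


class InclusionError(PipelineError):
    """An XML inclusion target is unresolvable or the chain is cyclic."""


class UnknownSettingError(PipelineError):
    """An override addresses a stage or setting that does not exist."""


class UnconnectedStreamError(PipelineError):
    """No upstream producer exists for a requested input stream."""


class IllegalReadError(PipelineError):
    """A stream request crosses domains sideways (disjoint coordinates)."""


class IllegalWriteError(PipelineError):
    """A module wrote data outside its own instance directory."""


class MissingOutputError(PipelineError):
    """A declared output stream produced no files."""


class DependencyNotReadyError(PipelineError):
    """Input placement requested before a source instance has completed."""


class SpecificationError(PipelineError):
    """An event or contrast specification is inconsistent."""


class ContrastWidthError(SpecificationError):
    """Expanded contrast width does not match the design width."""

    def __init__(self, expected: int, given: int, detail: str = ""):
        self.expected = expected
        self.given = given
        msg = f"contrast width mismatch: expected {expected} columns, got {given}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class RemoteConnectionError(PipelineError):
    """A remote analysis tree could not be read or lacks the requested stream."""
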