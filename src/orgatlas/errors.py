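"""Exception hierarchy shared across the package."""


class OrgAtlasError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OrgAtlasError):
    """A file did not conform to its declared format or dialect."""


class DuplicateIdError(FormatError):
    """An identifier that must be unique occurred more than once."""


class InvariantError(OrgAtlasError):
    """A domain-type invariant was violated (bad coordinates, bad labels...)."""


class ConfigError(OrgAtlasError):
    """An invalid configuration object or parameter value."""


class PipelineError(OrgAtlasError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
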