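"""Exception hierarchy shared across the toolkit."""


class VsegError(Exception):
    """Base class for all toolkit errors."""


class FormatError(VsegError):
    """An input file violates its declared on-disk format."""


class UnsupportedFeatureError(FormatError):
    """The file is well formed but uses a feature the toolkit does not handle."""


class ParseError(VsegError):
    """Raw text/bytes could not be parsed into structured data at all.

    Distinct from validation failure: a document that parses but violates a
    data model yields violations, not this error.
    """


class ValidationFailure(VsegError):
    """A structured document violates a data model."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations) or "invalid document")


class NotFoundError(VsegError):
    """A requested entry, member, or pointer does not exist."""


class ConflictError(VsegError):
    """The operation would overwrite something that already exists."""


class ContractError(VsegError):
    """Internal consistency violated (e.g. metadata does not match payloads)."""
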