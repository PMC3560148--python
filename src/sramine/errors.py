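"""Exception hierarchy for sramine."""


class SramineError(Exception):
    """Base class for all package-specific errors."""


class SraXmlError(SramineError):
    """Malformed or structurally unexpected SRA XML."""


class KindMismatchError(SraXmlError):
    """Document root does not match the requested entity kind."""


class RecordError(SraXmlError):
    """One or more records in a document are invalid (e.g. missing accession)."""

    def __init__(self, message, aliases=()):
        super().__init__(message)
        self.aliases = list(aliases)


class StoreError(SramineError):
    """Metadata store creation/ingestion problem."""


class QuerySyntaxError(SramineError):
    """Full-text query expression could not be parsed."""


class UnknownColumnError(SramineError):
    """A column-qualified query names a column absent from the denormalized table."""


class ReadOnlyError(SramineError):
    """A write statement was passed to the read-only SQL interface."""


class FetchError(SramineError):
    """Network retrieval failed after the configured number of attempts."""


class FeatureUnavailableError(SramineError):
    """An optional feature's external dependency is not present."""


class IGVError(SramineError):
    """IGV socket connection or command failure."""
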