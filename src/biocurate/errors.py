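"""Exception hierarchy for the curation framework.

Validation problems on user-built queries are reported as *data* (lists of
violation strings) by :func:`biocurate.query.validate`; exceptions are raised
only once an operation cannot produce its result.
"""

from __future__ import annotations


class BiocurateError(Exception):
    """Base class for all framework errors."""


class ValidationError(BiocurateError):
    """A query failed validation; carries the individual violations."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid query: " + "; ".join(violations))


class UnsupportedRepositoryError(BiocurateError):
    """The requested repository cannot serve this kind of request."""


class MalformedIdError(BiocurateError):
    """A record identifier does not match the repository's id format."""


class RetrievalError(BiocurateError):
    """A transport failed to deliver a document; carries the URL."""

    def __init__(self, url: str, reason: str):
        self.url = url
        self.reason = reason
        super().__init__(f"retrieval failed for {url}: {reason}")


class ParseError(BiocurateError):
    """A document could not be syntactically analysed."""


class DialectError(ParseError):
    """The document is well formed but not in the expected dialect."""


class TruncationError(ParseError):
    """A binary payload is shorter than its own header promises."""


class FormatError(ParseError):
    """The payload matches no recognised dialect of the format."""


class ManifestError(BiocurateError):
    """A column manifest does not line up with the table it describes."""


class SchemaError(BiocurateError):
    """An entity or association violates the registered schema."""


class QLSyntaxError(BiocurateError):
    """The SQL-like statement failed to parse; carries a character offset."""

    def __init__(self, message: str, offset: int):
        self.offset = offset
        super().__init__(f"{message} (at offset {offset})")


class StoreError(BiocurateError):
    """The persistent store cannot carry out the operation."""


class RenderError(BiocurateError):
    """No card layout is registered for this entity kind."""
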