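"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`EolkitError`,
so callers (and the CLI) can distinguish operational failures from bugs.
"""


class EolkitError(Exception):
    """Base class for all package errors."""


class ContractError(EolkitError, ValueError):
    """A precondition or type invariant was violated by the caller."""


class TransportError(EolkitError):
    """The transport failed to complete a request (network-level failure)."""


class DocumentNotFoundError(EolkitError, LookupError):
    """No document is available at the requested URL."""

    def __init__(self, url: str, message: str | None = None):
        self.url = url
        super().__init__(message or f"no document found for URL: {url}")


class ParseError(EolkitError):
    """The document is not well-formed XML."""


class DialectError(EolkitError):
    """Well-formed XML, but not in the expected response dialect."""


class ResolutionError(EolkitError):
    """One or more identifiers or taxon names could not be resolved.

    ``failures`` maps the offending id/name to a short reason.
    """

    def __init__(self, failures: dict):
        self.failures = dict(failures)
        detail = "; ".join(f"{k!r}: {v}" for k, v in self.failures.items())
        super().__init__(f"could not resolve {len(self.failures)} item(s): {detail}")


class ProviderNotFoundError(EolkitError, LookupError):
    """A page has no hierarchy entry from the requested provider."""

    def __init__(self, taxon: str, wanted: str, available: list):
        self.taxon = taxon
        self.wanted = wanted
        self.available = list(available)
        super().__init__(
            f"page for {taxon!r} has no entry from provider {wanted!r}; "
            f"available providers: {self.available or '(none)'}"
        )


class AmbiguityError(EolkitError):
    """Duplicate names prevent an unambiguous join or match."""

    def __init__(self, duplicates: list, context: str = ""):
        self.duplicates = list(duplicates)
        msg = f"duplicate names: {self.duplicates}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class MissingDataError(EolkitError):
    """Missing rank cells block tree construction under the chosen policy."""

    def __init__(self, cells: list, message: str | None = None):
        self.cells = list(cells)
        super().__init__(message or f"missing (taxon, rank) cells: {self.cells}")


class RankOrderError(EolkitError):
    """Classification pages imply contradictory (cyclic) rank orderings."""

    def __init__(self, cycle: list):
        self.cycle = list(cycle)
        super().__init__(f"rank order conflict involving: {self.cycle}")


class ConsistencyError(EolkitError):
    """A tree and the matrix it was supposedly built from do not agree."""
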