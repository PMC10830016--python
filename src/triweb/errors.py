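"""Exception hierarchy.

All triweb errors derive from :class:`TriwebError` so callers can catch the
package's failures in one clause while letting programming errors propagate.
"""


class TriwebError(Exception):
    """Base class for all triweb errors."""


class ParseError(TriwebError):
    """A network file is malformed; the message names the offending line."""


class StructuralError(TriwebError):
    """The network violates a structural invariant (shared set, topology, layer compatibility)."""


class NodeReferenceError(TriwebError):
    """An edge endpoint does not belong to any declared species set."""


class ConfigurationError(TriwebError):
    """An operation was called with an inconsistent or incomplete configuration."""


class DomainError(TriwebError):
    """A quantity is undefined for the given input (e.g. PC of a non-connector)."""


class GenerationError(TriwebError):
    """The synthetic generator could not satisfy its targets within bounded retries."""


class RandomizationError(TriwebError):
    """A null model could not produce a valid replicate within bounded retries."""
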