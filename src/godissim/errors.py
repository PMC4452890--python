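"""Exception hierarchy.

``NASignal`` subclasses mark conditions that a query layer should render as
the ``NA`` category (a term that exists but annotates nothing in the species,
an unknown/obsolete term, an empty eligibility pool) — as opposed to genuine
input errors, which stay hard failures.
"""


class GodissimError(Exception):
    """Base class for all package errors."""


class ParseError(GodissimError):
    """Unrecoverable problem in an input file (bad stanza, zero usable rows)."""


class NASignal(GodissimError):
    """A statistic cannot be computed for this pair; render as NA, not a crash."""


class UnknownTermError(NASignal, KeyError):
    """GO identifier absent from the ontology (after alt_id resolution)."""


class ObsoleteTermError(NASignal):
    """GO term is obsolete; it annotates no current protein."""


class NotAnnotatedError(NASignal):
    """GO term annotates no protein of the species under study."""


class EmptyPoolError(NASignal):
    """The eligible pool (proteins or edges) for this namespace combination is empty."""
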