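"""Exception hierarchy.

All package errors derive from :class:`HareSelectError` so callers can catch
one base class; subclasses distinguish format problems, value-level
validation, lookup failures and degenerate statistical inputs.
"""


class HareSelectError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(HareSelectError):
    """A table is structurally wrong (missing column, bad header)."""


class ValidationError(HareSelectError):
    """A value violates an invariant (range, sum, vocabulary)."""


class CompositionLookupError(HareSelectError):
    """No composition profile for a (taxon, season) that availability needs."""


class AmbiguousGroupError(HareSelectError):
    """A dual-membership taxon was looked up without a context tag."""


class UnknownTaxonError(HareSelectError):
    """A taxon is absent from the taxon-to-group mapping."""


class DegenerateDietError(HareSelectError):
    """Total use is zero: Manly's alpha is undefined."""


class DegenerateInputError(HareSelectError):
    """An input is formally valid but carries no information (all-zero DM)."""


class UndefinedIndexError(HareSelectError):
    """Chesson's electivity is undefined (fewer than 2 available items)."""


class PairingError(HareSelectError):
    """Two per-individual tables do not cover the same individuals."""


class ConfigError(HareSelectError):
    """The run configuration is incomplete or out of range."""
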