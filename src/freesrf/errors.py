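"""Exception hierarchy.

All package errors derive from :class:`FreeSRFError` so callers (and the CLI)
can distinguish configuration mistakes, bad scientific input, and lookup
failures from genuine bugs.
"""


class FreeSRFError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FreeSRFError):
    """An override or configuration key names something that does not exist."""


class ValidationError(FreeSRFError, ValueError):
    """A value violates a physical or structural invariant (e.g. non-positive)."""


class LookupMissError(FreeSRFError, KeyError):
    """A residue, element or ion symbol is absent from the reference tables."""


class EmptyInputError(FreeSRFError, ValueError):
    """A sequence or composition is empty where content is required."""


class DomainError(FreeSRFError, ValueError):
    """A numeric argument lies outside the physically meaningful domain."""


class NonPhysicalDensityError(DomainError):
    """The Clausius-Mossotti sum reaches or exceeds 1 (no real refractive index)."""


class DegenerateInversionError(DomainError):
    """The forward map is not invertible (zero concentration or polarizability)."""
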