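"""Exception hierarchy shared across the package."""


class CrossFdrError(Exception):
    """Base class for all crossfdr errors."""


class ValidationError(CrossFdrError, ValueError):
    """A value or table failed an invariant check."""


class FormatError(CrossFdrError, ValueError):
    """An input file does not conform to the expected layout."""


class EmptyInputError(CrossFdrError, ValueError):
    """An operation received (or produced) no usable rows."""


class ConfigurationError(CrossFdrError, ValueError):
    """Required configuration (e.g. MAF for pruning) is missing or inconsistent."""


class InstrumentError(CrossFdrError, ValueError):
    """One or more MR instruments are unusable (e.g. zero exposure effect)."""
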