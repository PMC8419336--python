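"""Exception hierarchy shared across the package."""


class VafTreeError(Exception):
    """Base class for all vaftree errors."""


class ValidationError(VafTreeError):
    """Invalid input data or malformed domain object."""


class EnumerationLimitError(VafTreeError):
    """Requested exhaustive enumeration would exceed the configured limit."""


class FitError(VafTreeError):
    """The constrained least-squares fit failed numerically."""
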