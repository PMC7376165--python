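"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file violates the expected on-disk format (bad cell, duplicate ID...)."""


class InsufficientDataError(ValueError):
    """Too few observations remain after filtering to carry out the analysis."""


class CapacityError(RuntimeError):
    """An exact combinatorial search would exceed the configured guard."""
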