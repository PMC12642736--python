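"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input table, configuration, or argument is invalid."""


class ConsistencyError(ValidationError):
    """Raised when inputs are internally contradictory.

    Examples: an isoform mapped to two genes, or more phased than total reads.
    """
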