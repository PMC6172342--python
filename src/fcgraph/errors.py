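"""Shared exception types."""


class DegenerateInputError(ValueError):
    """A time series is constant (zero variance) where variance is required."""


class EmptyParcellationError(RuntimeError):
    """No cluster survived filtering; the parcellation would be empty."""
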