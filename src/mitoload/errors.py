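"""Exception hierarchy shared across the pipeline.

``InputError`` covers malformed or inconsistent input data; ``ComputationError``
covers estimates that cannot be formed from valid input (zero synonymous
diversity, saturated distances, degenerate bootstrap). The CLI maps them to
distinct exit codes.
"""


class MitoloadError(Exception):
    """Base class for all package errors."""


class InputError(MitoloadError):
    """Malformed, inconsistent or missing input data."""


class ComputationError(MitoloadError):
    """A requested estimate is undefined for the given (valid) input."""
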