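"""Exception hierarchy shared across nucleodyn modules."""


class NucleodynError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NucleodynError, ValueError):
    """A parameter set violates its invariants (positivity, ordering, sum rules)."""


class InputError(NucleodynError, ValueError):
    """Malformed or out-of-contract input data."""


class DegenerateTraceError(InputError):
    """An intensity trace carries no usable signal (zero mean, constant, ...)."""


class NonIdentifiableError(NucleodynError):
    """The data cannot constrain the model (all-zero ACF, amplitude sum >= 1, ...)."""


class ConfigurationError(NucleodynError, ValueError):
    """A simulation or workflow configuration is invalid or numerically unstable."""


class DegenerateInputError(InputError):
    """An image analysis region is empty or has a non-positive mean."""


class PlacementError(NucleodynError, RuntimeError):
    """Synthetic foci could not be placed under the non-overlap constraint."""


class ValidationError(InputError):
    """A file failed strict format validation; message carries the diagnostic."""
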