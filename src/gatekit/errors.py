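"""Exception hierarchy shared across the package."""


class GatekitError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(GatekitError, ValueError):
    """A caller-supplied value is outside the valid domain (non-finite,
    negative concentration, non-positive sigma, ...)."""


class ConfigurationError(GatekitError):
    """A mechanism, parameter set, or run configuration is inconsistent,
    e.g. a transition references a rate name with no value."""


class ReducibilityError(GatekitError):
    """The rate matrix has more than one near-zero eigenvalue, i.e. the
    chain splits into several communicating classes and no unique
    stationary distribution exists."""


class NumericalFailureError(GatekitError):
    """A spectral decomposition or reconstruction failed its tolerance
    checks (defective matrix, large imaginary residue, ...)."""


class DegenerateConditionError(GatekitError):
    """A normalisation is impossible under the requested conditions,
    e.g. zero open probability in the blocker-free reference."""


class FitFailureError(GatekitError):
    """A least-squares optimisation did not converge."""


class RundownCorrectionError(GatekitError):
    """Rundown correction was requested but the dataset carries too few
    reference sweeps to estimate the drift."""


class SchemaError(GatekitError):
    """A data file does not match the expected column layout."""


class ParseError(GatekitError):
    """A data file contains cells that cannot be parsed; the message
    carries the offending location."""
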