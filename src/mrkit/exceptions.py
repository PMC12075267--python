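"""Exception types shared across the package."""


class MRKitError(Exception):
    """Base class for package-specific errors."""


class ConfigError(MRKitError, ValueError):
    """Invalid configuration: missing columns, out-of-range thresholds, bad files."""


class EstimationImpossibleError(MRKitError, ValueError):
    """No estimate can be produced (too few instruments, empty harmonized set)."""


class ConvergenceError(MRKitError, RuntimeError):
    """An iterative fit failed to converge (e.g. separation in a logistic fit)."""
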