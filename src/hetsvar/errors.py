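"""Exception hierarchy shared across the pipeline."""


class HetsvarError(Exception):
    """Base class for all package errors."""


class ConfigError(HetsvarError):
    """A parameter or configuration value is invalid."""


class DataError(HetsvarError):
    """Input data violate a documented invariant."""


class EstimationError(HetsvarError):
    """A model fit or solve failed (degenerate design, no root, instability)."""


class IdentificationError(EstimationError):
    """The moment system is not identified (e.g. homogeneous volatility regimes)."""
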