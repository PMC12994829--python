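"""Exception hierarchy shared across the model."""


class PfoCeaError(Exception):
    """Base class for all package errors."""


class ConfigError(PfoCeaError):
    """Configuration file could not be parsed or contains unknown keys."""


class ValidationError(PfoCeaError):
    """A parameter value violates a model invariant."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "parameter validation failed:\n"
            + "\n".join(f"  - {v}" for v in self.violations)
        )


class CalibrationError(PfoCeaError):
    """Life-table calibration could not bracket the target."""


class ModelError(PfoCeaError):
    """The cohort simulation reached an inconsistent state."""


class DistributionError(PfoCeaError):
    """Requested moments are infeasible for the distribution family."""
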