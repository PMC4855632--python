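"""Exception hierarchy shared across the package."""


class DevPlanError(Exception):
    """Base class for all package errors."""


class ValidationError(DevPlanError, ValueError):
    """An input violates a documented precondition (exit code 2 in the CLI)."""


class InfeasibleDesignError(DevPlanError, RuntimeError):
    """No design satisfying the error constraints exists within the search
    bounds (exit code 3 in the CLI)."""


class ConfigurationError(DevPlanError, RuntimeError):
    """A numerical search (e.g. the maximum-information root search) could not
    be completed for the requested configuration."""
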