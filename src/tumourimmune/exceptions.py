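"""Exception hierarchy shared across the package."""


class TumourImmuneError(Exception):
    """Base class for all package-specific errors."""


class ScenarioError(TumourImmuneError, ValueError):
    """Unknown scenario label or an invalid scenario/parameter definition."""


class ConfigError(TumourImmuneError, ValueError):
    """Malformed or invalid configuration file/override."""


class IntegrationError(TumourImmuneError, RuntimeError):
    """The ODE integrator failed (blow-up, non-finite state, undershoot)."""


class AbmError(TumourImmuneError, RuntimeError):
    """A stochastic run failed (overflow guard, invalid state)."""


class ComparisonError(TumourImmuneError, ValueError):
    """Trajectories cannot be compared (grid/model mismatch, empty input)."""
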