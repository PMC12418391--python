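"""Exception hierarchy for mirpulse."""


class MirpulseError(Exception):
    """Base class for all mirpulse errors."""


class ParameterError(MirpulseError):
    """Invalid kinetic parameter or state value; the message names the field."""


class SteadyStateError(MirpulseError):
    """Steady-state computation failed or violated the uniqueness guarantee."""


class IntegrationError(MirpulseError):
    """ODE integration failed; carries the failing time in the message."""


class DegenerateEquilibrationError(MirpulseError):
    """The system starts (and stays) at steady state, so the equilibration
    time — and with it the admissible frequency grid 1/tau — is undefined."""


class ConfigError(MirpulseError):
    """Malformed or inconsistent run configuration."""
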