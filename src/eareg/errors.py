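"""Exception hierarchy for the registration pipeline."""


class EaregError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EaregError, ValueError):
    """An argument violates an operation's contract (bad shapes, empty sets, ...)."""


class ConfigurationError(EaregError, ValueError):
    """An unknown backend, bad config value, or malformed config/scene file."""


class InvalidSceneError(EaregError, ValueError):
    """A synthetic-scene request whose side transforms are geometrically inconsistent."""


class RegistrationFailureError(EaregError, RuntimeError):
    """A pipeline stage could not produce a usable result.

    The ``stage`` attribute names the failing stage so CLI error messages can
    point at it.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"registration-failure [{stage}]: {message}")
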