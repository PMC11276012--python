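"""Exception types shared across the package."""


class AquabridgeError(Exception):
    """Base class for package errors."""


class ParseError(AquabridgeError):
    """A structure or trajectory file could not be parsed."""


class EmptyModelError(AquabridgeError):
    """A structure file contained no atoms."""


class TopologyMismatchError(AquabridgeError):
    """Trajectory atom count does not match the topology."""


class EmptySelectionError(AquabridgeError):
    """An atom selection resolved to zero atoms."""


class NoEventError(AquabridgeError):
    """An indicator series contains no events (h identically zero)."""

    def __init__(self, msg: str, mean_occupancy: float = 0.0):
        super().__init__(msg)
        self.mean_occupancy = mean_occupancy


class ContractViolationError(AquabridgeError):
    """An input violates a documented precondition (e.g. C(0) != 1)."""


class InsufficientReplicatesError(AquabridgeError):
    """A statistical comparison requires >= 2 replicas per group."""


class ConfigError(AquabridgeError):
    """Run configuration is invalid or inconsistent."""


class TruncationWarning(UserWarning):
    """A trajectory ended mid-frame; complete frames were yielded."""
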