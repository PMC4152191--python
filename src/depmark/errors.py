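"""Exception hierarchy for the depmark pipeline."""


class DepmarkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DepmarkError):
    """A scenario configuration is missing, malformed, or violates an invariant."""


class InfeasibleParametersError(DepmarkError):
    """Named per-cycle transition probabilities from one state exceed 1."""

    def __init__(self, state: str, total: float):
        self.state = state
        self.total = total
        super().__init__(
            f"named transitions out of state '{state}' sum to {total:.6g} > 1"
        )


class InfeasibleMomentsError(DepmarkError):
    """Moments cannot be matched by the requested distribution family."""
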