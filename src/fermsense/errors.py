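"""Exception hierarchy for fermsense."""


class FermsenseError(Exception):
    """Base class for all fermsense errors."""


class InvalidInputError(FermsenseError):
    """Malformed or inconsistent input data (shapes, ordering, schema)."""


class ParameterError(FermsenseError):
    """Strain or model parameters outside their valid domain."""


class DomainError(FermsenseError):
    """A quantity left the mathematical domain of an operation."""


class SimulationError(FermsenseError):
    """The cultivation ODE integrator failed."""


class TrainingDivergedError(FermsenseError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training diverged (non-finite loss) at epoch {epoch}")


class ContractError(FermsenseError):
    """A cross-component contract was violated (feature sets, grids, weights)."""
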