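"""Exception hierarchy for condyn."""


class CondynError(Exception):
    """Base class for all condyn errors."""


class InvalidLatentError(CondynError):
    """Latent vector violates log-normal support (non-positive, non-finite, too short)."""


class InvalidAdjacencyError(CondynError):
    """Adjacency matrix violates symmetry / sign / zero-diagonal requirements."""


class InvalidLaplacianError(CondynError):
    """Graph Laplacian violates its structural invariants."""


class InsufficientDataError(CondynError):
    """Too few longitudinal observations to form the requested windows."""


class DivergenceError(CondynError):
    """Training produced a non-finite loss.

    Carries the epoch index at which divergence was detected.
    """

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class UndefinedCorrelationError(CondynError):
    """Pearson correlation is undefined (constant input vector)."""
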