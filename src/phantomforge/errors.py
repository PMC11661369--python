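"""Exception hierarchy shared across phantomforge modules."""


class PhantomforgeError(Exception):
    """Base class for all package-specific errors."""


class InsufficientDataError(PhantomforgeError):
    """Too few records to perform the requested fit."""


class RankDeficiencyError(PhantomforgeError):
    """The regression design matrix is rank deficient (collinear ratios)."""

    def __init__(self, message: str, direction=None):
        super().__init__(message)
        #: unit vector in (Rg, Rw, 1) space along which the design is degenerate
        self.direction = direction


class DomainError(PhantomforgeError):
    """An input value lies outside the mathematically valid domain."""


class InfeasibleDesignError(PhantomforgeError):
    """One or more phantom regions cannot be realized by the mixing model."""

    def __init__(self, message: str, regions=None):
        super().__init__(message)
        self.regions = list(regions) if regions is not None else []


class UnsupportedDialectError(PhantomforgeError):
    """G-code uses a dialect feature outside the supported subset."""


class PlanningError(PhantomforgeError):
    """Purge-tower planning or insertion cannot proceed consistently."""


class MeshingError(PhantomforgeError):
    """Surface mesh construction failed for a region."""
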