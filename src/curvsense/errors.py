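"""Exception and warning types used across the package."""


class CurvSenseError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(CurvSenseError):
    """Buckle geometry violates a constraint (e.g. self-intersecting offset surface)."""


class InsufficientSamplingError(CurvSenseError):
    """Too few beads/points for the requested fit basis."""


class DegenerateFitError(CurvSenseError):
    """Rank-deficient least-squares design.

    Carries the names of the basis functions that cannot be resolved from
    the supplied points.
    """

    def __init__(self, message, deficient=()):
        super().__init__(message)
        self.deficient = tuple(deficient)


class AmbiguousLeafletError(CurvSenseError):
    """Point equidistant from both leaflet surfaces within tolerance."""


class BinMismatchError(CurvSenseError):
    """Two distributions do not share bin edges."""


class EmptyDistributionError(CurvSenseError):
    """Distribution with no mass where mass is required."""


class ConfigError(CurvSenseError):
    """Invalid run configuration; message lists the offending fields."""


class MaskedMassWarning(UserWarning):
    """Sampled mass fell in bins outside the accessible support."""
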