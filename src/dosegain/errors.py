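"""Exception hierarchy for the dosegain pipeline."""


class DoseGainError(Exception):
    """Base class for all dosegain errors."""


class InvalidDVHError(DoseGainError, ValueError):
    """A dose-volume histogram violates its structural invariants."""


class UnitError(DoseGainError, ValueError):
    """Dose or volume units of two quantities do not agree."""


class DegenerateStructureError(DoseGainError, ValueError):
    """A structure with zero volume cannot carry a dose deviation."""


class MissingStructureError(DoseGainError, KeyError):
    """A weighted structure has no MADD available."""


class DegenerateTestError(DoseGainError, ValueError):
    """A statistical test is undefined for the given data (e.g. zero variance)."""


class EmptySubgroupError(DoseGainError, ValueError):
    """A subgroup predicate selected no patients."""


class RankDeficiencyError(DoseGainError, ValueError):
    """The regression design matrix is rank deficient (constant predictor)."""


class InsufficientDataError(DoseGainError, ValueError):
    """Too few complete cases to fit the requested model."""


class TransformError(DoseGainError, ValueError):
    """A predictor cannot be power-transformed (non-positive after shift)."""


class CodingError(DoseGainError, ValueError):
    """A categorical value is outside the declared level set."""


class ConfigError(DoseGainError, ValueError):
    """A generator or pipeline configuration is invalid."""
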