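"""Exception hierarchy shared across the package."""


class FetalGrowthError(Exception):
    """Base class for package errors."""


class ParameterError(FetalGrowthError, ValueError):
    """A parameter vector or argument has the wrong shape, count, or value."""


class DataError(FetalGrowthError, ValueError):
    """Input data are insufficient or malformed for the requested operation."""


class DomainError(FetalGrowthError, ValueError):
    """A quantity lies outside its mathematical domain (e.g. adult volume <= 0)."""


class DesignError(FetalGrowthError, ValueError):
    """A statistical design matrix is rank deficient or a covariate is inestimable."""


class SelectionError(FetalGrowthError, RuntimeError):
    """No candidate model family converged; model selection is impossible."""


class ExtractionError(FetalGrowthError, RuntimeError):
    """Surface extraction failed (e.g. empty cortical plate or interior mask)."""


class GeometryError(FetalGrowthError, ValueError):
    """Phantom or mesh geometry parameters are inconsistent."""
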