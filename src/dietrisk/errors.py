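"""Exception types shared across the pipeline."""


class DietriskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DietriskError):
    """A configuration field is invalid; the message names the field."""


class SpecificationError(DietriskError):
    """An effect specification refers to an unknown nutrient or is malformed."""


class StratificationError(DietriskError):
    """Too few values (or groups) to stratify."""


class FittingError(DietriskError):
    """A model fit failed to converge or the data are degenerate."""


class SplineError(DietriskError):
    """Spline basis or fit cannot be constructed from the given data."""


class CovariateError(DietriskError):
    """Covariate schema mismatch between a fitted model and new data."""


class FixtureError(DietriskError):
    """A packaged printed-table fixture cell cannot be parsed."""
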