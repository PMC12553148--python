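"""Exception hierarchy used across the package."""


class GaitFosrError(Exception):
    """Base class for all package errors."""


class ValidationError(GaitFosrError, ValueError):
    """Malformed or inconsistent input data."""


class CovariateRangeError(GaitFosrError, ValueError):
    """A covariate value falls outside the supported (training) range."""


class DegenerateInputError(GaitFosrError, ValueError):
    """Input is degenerate for the requested computation (e.g. two
    constant curves for a range-normalised metric)."""


class NumericalError(GaitFosrError, RuntimeError):
    """A numerical routine failed (singularity, non-convergence)."""
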