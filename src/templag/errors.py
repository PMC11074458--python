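"""Exception types shared across the package."""


class TemplagError(Exception):
    """Base class for all package-specific errors."""


class SpecError(TemplagError, ValueError):
    """An invalid basis / model specification."""


class SchemaError(TemplagError, ValueError):
    """An input table does not match the required daily-series schema."""


class ConstantVariableError(TemplagError, ValueError):
    """A variable is constant, so a spline basis or rank correlation is undefined."""


class SingularDesignError(TemplagError, ValueError):
    """The design matrix is rank-deficient after stratum centering."""


class ConvergenceError(TemplagError, RuntimeError):
    """The fitting algorithm did not converge within the iteration cap."""


class ExtrapolationError(TemplagError, ValueError):
    """Requested evaluation outside the observed exposure range without opting in."""
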