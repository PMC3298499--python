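"""Exception and warning types shared across the package."""


class InputDataError(ValueError):
    """The supplied data violate a structural precondition (missing values,
    wrong shape, rank deficiency, non-numeric cells, ...)."""


class ParameterError(ValueError):
    """A user-supplied parameter is outside its admissible range."""


class DegenerateInputError(ValueError):
    """The input is structurally valid but degenerate for the requested
    operation (zero variance, coincident centroids, zero singular value)."""


class ConvergenceWarning(UserWarning):
    """An iterative algorithm stopped at ``max_iter`` without reaching its
    tolerance; results are returned with ``converged=False``."""
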