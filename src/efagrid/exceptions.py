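"""Exception hierarchy shared across the package."""


class EfagridError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(EfagridError):
    """Input data are degenerate (e.g. a zero-variance column)."""


class NotPositiveDefiniteError(EfagridError):
    """A correlation matrix is not positive definite and smoothing was disabled."""


class SingularMatrixError(EfagridError):
    """A correlation matrix is singular; squared multiple correlations need an inverse."""


class NegativeEigenvalueError(EfagridError):
    """One of the m largest eigenvalues of the reduced correlation matrix is negative.

    Raised only when the eigenvalue treatment keeps raw (signed) eigenvalues;
    callers may rerun with a different communality seed (the fallback policy).
    """


class CollinearFactorsError(EfagridError):
    """The least-squares system of the oblique transformation is singular."""


class UndefinedCongruenceError(EfagridError):
    """Factor congruence is undefined for an all-zero loading column."""


class ParseError(EfagridError):
    """A population-model code does not match the p|m|lambda[|c] grammar."""
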