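"""Correlation-matrix construction, validation and conditioning.

Everything downstream of this module consumes a :class:`CorrelationMatrix`:
a symmetric matrix of Pearson correlations with an exactly-unit diagonal.
The module also provides the two classic communality seed estimators used
by iterative principal axis factoring — squared multiple correlations (SMC)
and maximum absolute correlations (MAC) — and eigenvalue smoothing for
matrices that are not positive definite (e.g. correlation matrices pooled
from published tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateInputError,
    NotPositiveDefiniteError,
    SingularMatrixError,
)

#: smallest eigenvalue for a matrix to count as positive definite
PD_TOLERANCE = 1e-8

#: symmetry tolerance accepted at construction
_SYM_TOL = 1e-12


@dataclass(frozen=True)
class CorrelationMatrix:
    """A validated p x p indicator intercorrelation matrix.

    Parameters
    ----------
    values
        Square array of correlations. Must be symmetric within 1e-12 with a
        diagonal of ones; the stored matrix is exactly symmetrized and its
        diagonal is set to exactly 1.
    indicator_names
        Optional names, one per indicator. Defaults to ``V1 .. Vp``.
    """

    values: np.ndarray
    indicator_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"correlation matrix must be square, got shape {v.shape}")
        p = v.shape[0]
        if p < 2:
            raise ValueError("a correlation matrix needs at least 2 indicators")
        if np.max(np.abs(v - v.T)) > _SYM_TOL:
            raise ValueError("correlation matrix is not symmetric within 1e-12")
        if np.max(np.abs(np.diag(v) - 1.0)) > 1e-8:
            raise ValueError("correlation matrix diagonal must be 1")
        off = v[~np.eye(p, dtype=bool)]
        if off.size and (np.min(off) < -1.0 - 1e-12 or np.max(off) > 1.0 + 1e-12):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 1.0)
        v.flags.writeable = False
        object.__setattr__(self, "values", v)
        names = tuple(self.indicator_names) or tuple(f"V{i + 1}" for i in range(p))
        if len(names) != p:
            raise ValueError("number of indicator names must match matrix order")
        object.__setattr__(self, "indicator_names", names)

    @property
    def p(self) -> int:
        return self.values.shape[0]

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_csv(cls, path) -> "CorrelationMatrix":
        """Read a square correlation CSV (header row and index column = names)."""
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("correlation CSV must have matching row and column names")
        return cls(df.to_numpy(dtype=float), tuple(str(c) for c in df.columns))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.indicator_names, columns=self.indicator_names)


def correlation_from_raw(data, indicator_names=None) -> CorrelationMatrix:
    """Pearson correlation matrix of an n x p raw data matrix.

    Raises
    ------
    DegenerateInputError
        If ``n < 3`` or any column has zero variance (the offending column
        is named in the message).
    """
    if isinstance(data, pd.DataFrame):
        if indicator_names is None:
            indicator_names = tuple(str(c) for c in data.columns)
        data = data.to_numpy(dtype=float)
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("raw data must be a 2-d array (observations x indicators)")
    n, p = x.shape
    if n < 3:
        raise DegenerateInputError("at least 3 observations are required")
    names = tuple(indicator_names) if indicator_names else tuple(f"V{i + 1}" for i in range(p))
    sds = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0.0)
    if bad.size:
        raise DegenerateInputError(f"column '{names[bad[0]]}' has zero variance")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, names)


def is_positive_definite(R: CorrelationMatrix, tol: float = PD_TOLERANCE) -> bool:
    """True iff the smallest eigenvalue exceeds ``tol``."""
    return bool(np.linalg.eigvalsh(R.values)[0] > tol)


def smooth_to_pd(R: CorrelationMatrix, mode: str = "smooth") -> CorrelationMatrix:
    """Return a positive definite matrix highly similar to ``R``.

    mode="smooth"
        Eigendecompose, floor the eigenvalues at 1e-10 times the largest one,
        reconstruct, and rescale to a unit diagonal. A matrix that is already
        positive definite is returned unchanged, which makes the operation
        idempotent.
    mode="abort"
        Raise :class:`NotPositiveDefiniteError` on non-PD input instead
        (the behaviour of programs that refuse such matrices outright).
    """
    if mode not in ("smooth", "abort"):
        raise ValueError(f"unknown mode {mode!r}")
    if is_positive_definite(R):
        return R
    if mode == "abort":
        raise NotPositiveDefiniteError(
            "correlation matrix is not positive definite and smoothing is disabled"
        )
    S = R.values
    # floor keeps the smallest eigenvalue clear of the PD tolerance even
    # after the unit-diagonal rescale; repeat in case rescaling nudges an
    # eigenvalue back below it (rarely needed more than once)
    for _ in range(10):
        w, V = np.linalg.eigh(S)
        floor = max(1e-10 * w[-1], 10.0 * PD_TOLERANCE)
        w = np.maximum(w, floor)
        S = (V * w) @ V.T
        d = 1.0 / np.sqrt(np.diag(S))
        S = S * np.outer(d, d)
        S = (S + S.T) / 2.0
        np.fill_diagonal(S, 1.0)
        if np.linalg.eigvalsh(S)[0] > PD_TOLERANCE:
            break
    return CorrelationMatrix(S, R.indicator_names)


def smc(R: CorrelationMatrix) -> np.ndarray:
    """Squared multiple correlations: ``1 - 1 / diag(R^-1)``.

    The i-th entry is the R-squared from regressing indicator i on all
    other indicators; a standard initial communality estimate.
    """
    try:
        Rinv = np.linalg.inv(R.values)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError(
            "correlation matrix is singular; smooth it before computing SMCs"
        ) from exc
    d = np.diag(Rinv)
    if np.any(d <= 0):
        raise SingularMatrixError(
            "correlation matrix is numerically singular; smooth it before computing SMCs"
        )
    return np.clip(1.0 - 1.0 / d, 0.0, 1.0 - 1e-15)


def mac(R: CorrelationMatrix) -> np.ndarray:
    """Maximum absolute correlation of each indicator with any other one."""
    a = np.abs(R.values).copy()
    np.fill_diagonal(a, 0.0)
    return a.max(axis=1)
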