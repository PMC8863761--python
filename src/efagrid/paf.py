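"""Iterative principal axis factoring (PAF).

PAF repeatedly replaces the diagonal of the correlation matrix with the
current communality estimates, eigendecomposes the resulting "reduced"
matrix, rebuilds loadings from the m leading eigenpairs, and takes the row
sums of squared loadings as the next communality estimates. Statistical
programs differ in four places, all of which are settings here:

* the initial communalities (unity, maximum absolute correlation, or
  squared multiple correlations),
* whether eigenvalue magnitudes (absolute values) are used when taking
  square roots, which sidesteps failures on negative eigenvalues,
* whether convergence is judged on the change in the *sum* of all
  communalities or on the maximum change in any *single* communality,
* the convergence tolerance (1e-3 is the common default; 1e-6 a stricter
  alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .corrprep import CorrelationMatrix, mac, smc
from .exceptions import NegativeEigenvalueError

_INIT_METHODS = ("unity", "mac", "smc")
_CRITERION_TYPES = ("sum", "max_individual")
_FALLBACKS = ("unity", "mac", "error")


@dataclass(frozen=True)
class PAFSettings:
    """One configuration of the iterative PAF procedure.

    Attributes
    ----------
    init_comm
        Initial communality estimate: ``"unity"``, ``"mac"`` or ``"smc"``.
    abs_eigen
        Use absolute eigenvalue magnitudes when building loadings. With
        ``False`` the procedure fails if any of the m largest eigenvalues
        of the reduced matrix is negative.
    criterion_type
        ``"sum"`` compares the change in the sum of all communalities
        between iterations, ``"max_individual"`` the largest change in any
        single communality.
    criterion
        Convergence tolerance (default 1e-3).
    max_iter
        Iteration cap; non-convergence is reported, never silently truncated.
    smc_fail_fallback
        What to do when SMC seeds fail with a negative leading eigenvalue:
        rerun with ``"unity"`` or ``"mac"`` seeds, or ``"error"`` to
        propagate the failure (used in grid runs so failures are counted).
    """

    init_comm: str = "smc"
    abs_eigen: bool = True
    criterion_type: str = "sum"
    criterion: float = 1e-3
    max_iter: int = 5000
    smc_fail_fallback: str = "error"

    def __post_init__(self):
        if self.init_comm not in _INIT_METHODS:
            raise ValueError(f"init_comm must be one of {_INIT_METHODS}")
        if self.criterion_type not in _CRITERION_TYPES:
            raise ValueError(f"criterion_type must be one of {_CRITERION_TYPES}")
        if not self.criterion > 0:
            raise ValueError("criterion must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.smc_fail_fallback not in _FALLBACKS:
            raise ValueError(f"smc_fail_fallback must be one of {_FALLBACKS}")


@dataclass(frozen=True)
class UnrotatedSolution:
    """Result of a PAF extraction before rotation."""

    loadings: np.ndarray
    communalities: np.ndarray
    initial_communalities: np.ndarray
    iterations: int
    converged: bool
    eigenvalues_final: np.ndarray
    settings_used: PAFSettings
    fallback_used: str | None = None

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    @property
    def m(self) -> int:
        return self.loadings.shape[1]


def initial_communalities(R: CorrelationMatrix, method: str) -> np.ndarray:
    """Communality seeds for the chosen method (see :class:`PAFSettings`)."""
    if method == "unity":
        return np.ones(R.p)
    if method == "mac":
        return mac(R)
    if method == "smc":
        return smc(R)
    raise ValueError(f"unknown initial-communality method {method!r}")


def normalize_column_signs(L: np.ndarray) -> np.ndarray:
    """Flip column signs so each column's largest-magnitude entry is positive."""
    L = np.array(L, dtype=float)
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


def paf_extract(R: CorrelationMatrix, m: int, settings: PAFSettings | None = None) -> UnrotatedSolution:
    """Extract ``m`` factors from ``R`` by iterative principal axis factoring.

    Raises
    ------
    NegativeEigenvalueError
        If ``settings.abs_eigen`` is False and any of the m largest
        eigenvalues of the reduced matrix turns negative. The caller-level
        fallback policy (see :func:`paf_extract_with_fallback`) can rerun
        with different seeds.
    """
    settings = settings or PAFSettings()
    p = R.p
    if not 1 <= m < p:
        raise ValueError(f"number of factors must satisfy 1 <= m < p, got m={m}, p={p}")
    h0 = initial_communalities(R, settings.init_comm)
    h = h0.copy()
    W = R.values.copy()
    converged = False
    iterations = 0
    L = None
    lam_top = None
    tie_warned = False
    for iterations in range(1, settings.max_iter + 1):
        np.fill_diagonal(W, h)
        w, V = np.linalg.eigh(W)
        order = np.argsort(w)[::-1]  # raw eigenvalues, descending
        top = order[:m]
        lam_top = w[top]
        if not settings.abs_eigen and np.any(lam_top < 0):
            raise NegativeEigenvalueError(
                f"{int(np.sum(lam_top < 0))} of the {m} largest eigenvalues are negative "
                f"(init_comm={settings.init_comm!r}); rerun with abs_eigen=True or other seeds"
            )
        if not tie_warned and m < p:
            lam_next = w[order[m]]
            if abs(lam_top[-1] - lam_next) <= 1e-12 * max(1.0, abs(lam_top[-1])):
                warnings.warn(
                    "eigenvalue tie at the retention boundary; factor ordering is arbitrary",
                    RuntimeWarning,
                    stacklevel=2,
                )
                tie_warned = True
        L = V[:, top] * np.sqrt(np.abs(lam_top))
        h_new = np.sum(L**2, axis=1)
        if settings.criterion_type == "sum":
            delta = abs(h_new.sum() - h.sum())
        else:
            delta = np.max(np.abs(h_new - h))
        h = h_new
        if delta < settings.criterion:
            converged = True
            break
    L = normalize_column_signs(L)
    return UnrotatedSolution(
        loadings=L,
        communalities=h,
        initial_communalities=h0,
        iterations=iterations,
        converged=converged,
        eigenvalues_final=lam_top,
        settings_used=settings,
    )


def paf_extract_with_fallback(
    R: CorrelationMatrix, m: int, settings: PAFSettings | None = None
) -> UnrotatedSolution:
    """PAF with the configured rescue policy for failed SMC seeds.

    When SMC seeds fail with a negative leading eigenvalue and the fallback
    is ``"unity"`` or ``"mac"``, the extraction is rerun with those seeds;
    the returned solution records which fallback fired. With fallback
    ``"error"`` (grid runs) the failure propagates so it can be counted.
    """
    settings = settings or PAFSettings()
    try:
        return paf_extract(R, m, settings)
    except NegativeEigenvalueError:
        if settings.init_comm != "smc" or settings.smc_fail_fallback == "error":
            raise
        rerun = replace(settings, init_comm=settings.smc_fail_fallback)
        sol = paf_extract(R, m, rerun)
        return UnrotatedSolution(
            loadings=sol.loadings,
            communalities=sol.communalities,
            initial_communalities=sol.initial_communalities,
            iterations=sol.iterations,
            converged=sol.converged,
            eigenvalues_final=sol.eigenvalues_final,
            settings_used=settings,
            fallback_used=settings.smc_fail_fallback,
        )
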