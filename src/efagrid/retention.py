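"""Factor-number determination.

Two procedures: parallel analysis on the SMC-reduced correlation matrix
(the first empirical eigenvalue is tested against the 95th percentile of
the random eigenvalues, later ones against the random means), and the
admissibility-driven downward search used when an initial factor number
yields inadmissible solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corrprep import CorrelationMatrix, correlation_from_raw, smc
from .evaluate import is_admissible
from .exceptions import NegativeEigenvalueError
from .paf import paf_extract_with_fallback
from .popsim import ImplementationSpec, get_spec
from .rotate import rotate


@dataclass(frozen=True)
class ParallelAnalysisResult:
    """Eigenvalues and the retained factor count from parallel analysis."""

    empirical_eigenvalues: np.ndarray
    random_eigenvalue_p95_first: float
    random_eigenvalue_means: np.ndarray
    n_factors: int
    n_datasets: int


def _reduced_eigenvalues(R: CorrelationMatrix) -> np.ndarray:
    """Descending eigenvalues of R with SMCs on the diagonal."""
    W = R.values.copy()
    np.fill_diagonal(W, smc(R))
    return np.linalg.eigvalsh(W)[::-1]


def parallel_analysis(
    data=None,
    R: CorrelationMatrix | None = None,
    n: int | None = None,
    n_datasets: int = 1000,
    seed=None,
    percentile: float = 95.0,
) -> ParallelAnalysisResult:
    """Parallel analysis with SMC-reduced eigenvalues.

    Provide either a raw n x p ``data`` matrix or a correlation matrix ``R``
    together with its sample size ``n``. Random comparison data are standard
    normal of the same dimensions, reduced identically. The retained count
    is the largest k such that the first empirical eigenvalue exceeds the
    random 95th percentile and eigenvalues 2..k each exceed the
    corresponding random mean, stopping at the first failure.
    """
    if data is not None:
        data = np.asarray(data, dtype=float)
        n, p = data.shape
        R = correlation_from_raw(data)
    elif R is None or n is None:
        raise ValueError("provide either raw data or a correlation matrix with its n")
    p = R.p
    emp = _reduced_eigenvalues(R)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rand = np.empty((n_datasets, p))
    for d in range(n_datasets):
        x = rng.standard_normal((n, p))
        rand[d] = _reduced_eigenvalues(correlation_from_raw(x))
    first_p95 = float(np.percentile(rand[:, 0], percentile))
    means = rand.mean(axis=0)
    k = 0
    if emp[0] > first_p95:
        k = 1
        while k < p and emp[k] > means[k]:
            k += 1
    return ParallelAnalysisResult(
        empirical_eigenvalues=emp,
        random_eigenvalue_p95_first=first_p95,
        random_eigenvalue_means=means,
        n_factors=k,
        n_datasets=n_datasets,
    )


@dataclass(frozen=True)
class AdmissibilityStep:
    """One step of the downward admissibility search."""

    n_factors: int
    admissible_a: bool
    admissible_b: bool


@dataclass(frozen=True)
class AdmissibilitySearch:
    """Outcome of :func:`find_admissible`."""

    n_final: int  # 0 when no admissible solution exists at any n
    solution_a: object | None
    solution_b: object | None
    trace: tuple[AdmissibilityStep, ...]
    first_admissible_a: int  # 0 when spec A never produced an admissible solution
    first_admissible_b: int

    @property
    def all_inadmissible(self) -> bool:
        return self.n_final == 0


def _fit_pair(R: CorrelationMatrix, m: int, spec: ImplementationSpec):
    try:
        paf_sol = paf_extract_with_fallback(R, m, spec.paf)
    except NegativeEigenvalueError:
        return None, None, False
    rot_sol = rotate(paf_sol.loadings, spec.rot)
    return paf_sol, rot_sol, is_admissible(rot_sol, paf_sol)


def find_admissible(
    R: CorrelationMatrix,
    n_start: int,
    spec_a: ImplementationSpec | str,
    spec_b: ImplementationSpec | str,
) -> AdmissibilitySearch:
    """Decrement the factor count until both implementations are admissible.

    Both implementations are fitted at ``n_start`` factors; if either
    solution is inadmissible (a Heywood case, or a factor with fewer than
    two salient pattern coefficients) the count is reduced by one and both
    are refitted, until both are admissible or the count reaches zero.
    Each implementation's own first admissible count is recorded as well.
    """
    if n_start < 1:
        raise ValueError("n_start must be at least 1")
    spec_a = get_spec(spec_a)
    spec_b = get_spec(spec_b)
    trace = []
    first_a = first_b = 0
    for m in range(min(n_start, R.p - 1), 0, -1):
        paf_a, rot_a, ok_a = _fit_pair(R, m, spec_a)
        paf_b, rot_b, ok_b = _fit_pair(R, m, spec_b)
        trace.append(AdmissibilityStep(m, ok_a, ok_b))
        if ok_a and first_a == 0:
            first_a = m
        if ok_b and first_b == 0:
            first_b = m
        if ok_a and ok_b:
            return AdmissibilitySearch(
                n_final=m,
                solution_a=(paf_a, rot_a),
                solution_b=(paf_b, rot_b),
                trace=tuple(trace),
                first_admissible_a=first_a,
                first_admissible_b=first_b,
            )
    return AdmissibilitySearch(
        n_final=0,
        solution_a=None,
        solution_b=None,
        trace=tuple(trace),
        first_admissible_a=first_a,
        first_admissible_b=first_b,
    )
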