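"""Comparison and accuracy statistics for factor solutions.

Factor solutions are identified only up to column order and column sign, so
every comparison starts by aligning the fitted columns to a reference via
Tucker/Burt congruence. On aligned matrices this module computes the root
mean squared error against a known population pattern, element-wise
absolute-difference summaries between two fitted solutions, column
congruences, Heywood-case detection, the salient-loading map that defines
indicator-to-factor correspondence, and the admissibility rule (no Heywood
cases and at least two salient pattern coefficients per factor).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .exceptions import UndefinedCongruenceError
from .paf import UnrotatedSolution
from .rotate import RotatedSolution

#: a communality or loading at or beyond this magnitude marks a Heywood case
HEYWOOD_THRESHOLD = 0.998

#: pattern coefficients at or beyond this magnitude count as salient
SALIENCE_THRESHOLD = 0.20


@dataclass(frozen=True)
class FactorAlignment:
    """Column permutation and signs mapping fitted factors onto a reference."""

    permutation: tuple[int, ...]
    signs: tuple[int, ...]
    mean_congruence_after: float

    def apply(self, fitted: np.ndarray) -> np.ndarray:
        """Reorder and re-sign fitted columns to match the reference."""
        out = np.asarray(fitted, dtype=float)[:, list(self.permutation)]
        return out * np.asarray(self.signs, dtype=float)[None, :]


@dataclass(frozen=True)
class SolutionComparison:
    """Pairwise diff summary between two solutions at one analysis stage."""

    stage: str
    abs_diff_mean: float
    abs_diff_max: float
    congruence_mean: float
    congruence_min: float
    correspondence_diff_count: int


def factor_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker/Burt congruence: sum(x*y) / sqrt(sum(x^2) * sum(y^2)), in [-1, 1]."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("congruence requires vectors of equal length")
    nx = np.dot(x, x)
    ny = np.dot(y, y)
    if nx == 0.0 or ny == 0.0:
        raise UndefinedCongruenceError("congruence is undefined for a zero vector")
    return float(np.clip(np.dot(x, y) / np.sqrt(nx * ny), -1.0, 1.0))


def _congruence_matrix(fitted: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """C[i, j] = congruence(fitted column i, reference column j); 0 for zero columns."""
    fn = np.sqrt(np.sum(fitted**2, axis=0))
    rn = np.sqrt(np.sum(reference**2, axis=0))
    fn = np.where(fn == 0, np.inf, fn)
    rn = np.where(rn == 0, np.inf, rn)
    return (fitted / fn).T @ (reference / rn)


def align_factors(fitted: np.ndarray, reference: np.ndarray) -> FactorAlignment:
    """Match fitted columns to reference columns by maximal total |congruence|.

    Exhaustive over all m! permutations for m <= 6 (the scale of interest);
    greedy assignment on |congruence| beyond that. Signs are chosen so each
    matched congruence is non-negative.
    """
    fitted = np.asarray(fitted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fitted.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: fitted {fitted.shape} vs reference {reference.shape}"
        )
    m = fitted.shape[1]
    C = _congruence_matrix(fitted, reference)
    absC = np.abs(C)
    if m <= 6:
        best_perm, best_score = None, -np.inf
        for perm in permutations(range(m)):
            score = sum(absC[perm[j], j] for j in range(m))
            if score > best_score:
                best_score, best_perm = score, perm
        perm = best_perm
    else:
        perm = [-1] * m
        taken = set()
        # assign reference columns in order of their best available match
        order = np.argsort(-absC.max(axis=0))
        for j in order:
            cand = np.argsort(-absC[:, j])
            for i in cand:
                if i not in taken:
                    perm[j] = int(i)
                    taken.add(int(i))
                    break
        perm = tuple(perm)
    signs = tuple(1 if C[perm[j], j] >= 0 else -1 for j in range(m))
    mean_congr = float(np.mean([absC[perm[j], j] for j in range(m)]))
    return FactorAlignment(tuple(int(i) for i in perm), signs, mean_congr)


def rmse(reference: np.ndarray, fitted: np.ndarray, align: bool = True) -> float:
    """Root mean squared error between two p x m loading matrices.

    ``sqrt(trace((L - Lhat)' (L - Lhat)) / (p * m))``; with ``align=True``
    the fitted columns are first permuted/re-signed to best match the
    reference.
    """
    reference = np.asarray(reference, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if reference.shape != fitted.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs fitted {fitted.shape}"
        )
    if align:
        fitted = align_factors(fitted, reference).apply(fitted)
    diff = reference - fitted
    p, m = reference.shape
    return float(np.sqrt(np.trace(diff.T @ diff) / (p * m)))


def heywood_check(sol: UnrotatedSolution) -> bool:
    """True iff any communality or unrotated |loading| reaches 0.998."""
    return bool(
        np.any(sol.communalities >= HEYWOOD_THRESHOLD)
        or np.any(np.abs(sol.loadings) >= HEYWOOD_THRESHOLD)
    )


def salient_map(pattern: np.ndarray, threshold: float = SALIENCE_THRESHOLD) -> list[frozenset]:
    """Per-indicator set of factors with |pattern coefficient| >= threshold."""
    if not threshold > 0:
        raise ValueError("salience threshold must be positive")
    pattern = np.asarray(pattern, dtype=float)
    return [
        frozenset(int(j) for j in np.flatnonzero(np.abs(row) >= threshold))
        for row in pattern
    ]


def correspondence_diff(map_a, map_b, alignment: FactorAlignment | None = None) -> int:
    """Number of indicators whose salient-factor sets differ between two maps.

    If ``alignment`` is given it is the alignment of solution *b*'s factors
    onto solution *a*'s; b's factor labels are translated accordingly before
    comparing.
    """
    if len(map_a) != len(map_b):
        raise ValueError("salient maps must cover the same indicators")
    if alignment is not None:
        relabel = {old: new for new, old in enumerate(alignment.permutation)}
        map_b = [frozenset(relabel[f] for f in s) for s in map_b]
    return sum(1 for a, b in zip(map_a, map_b) if a != b)


def is_admissible(sol: RotatedSolution, paf: UnrotatedSolution) -> bool:
    """Admissibility: no Heywood case and >= 2 salient pattern loadings per factor."""
    if heywood_check(paf):
        return False
    salient = np.abs(sol.pattern) >= SALIENCE_THRESHOLD
    return bool(np.all(salient.sum(axis=0) >= 2))


def compare_loading_matrices(a: np.ndarray, b: np.ndarray, stage: str) -> SolutionComparison:
    """Diff statistics between two p x m loading/pattern matrices.

    b's columns are aligned to a's first; reports mean/max element-wise
    absolute difference, mean/min column congruence of the matched pairs,
    and the indicator-to-factor correspondence diff count.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    alignment = align_factors(b, a)
    b_aligned = alignment.apply(b)
    absdiff = np.abs(a - b_aligned)
    congr = [
        factor_congruence(a[:, j], b_aligned[:, j]) if np.any(a[:, j]) and np.any(b_aligned[:, j]) else 0.0
        for j in range(a.shape[1])
    ]
    count = correspondence_diff(salient_map(a), salient_map(b), alignment)
    return SolutionComparison(
        stage=stage,
        abs_diff_mean=float(absdiff.mean()),
        abs_diff_max=float(absdiff.max()),
        congruence_mean=float(np.mean(congr)),
        congruence_min=float(np.min(congr)),
        correspondence_diff_count=int(count),
    )


def compare_solutions(a, b, stage: str) -> SolutionComparison:
    """Compare two fitted solutions at one of the three analysis stages.

    ``stage`` selects the compared matrices: ``"unrotated"`` uses PAF
    loadings, ``"varimax"`` the varimax loadings, ``"promax"`` the promax
    pattern coefficients. ``a`` and ``b`` may be results objects exposing
    ``loadings`` / ``varimax_loadings`` / ``pattern``, or raw matrices.
    """
    getters = {
        "unrotated": "loadings",
        "varimax": "varimax_loadings",
        "promax": "pattern",
    }
    if stage not in getters:
        raise ValueError(f"stage must be one of {tuple(getters)}")

    def pick(sol):
        if isinstance(sol, np.ndarray):
            return sol
        return getattr(sol, getters[stage])

    return compare_loading_matrices(pick(a), pick(b), stage)
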