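"""Varimax and promax rotation in the variants implemented across programs.

Two varimax algorithms are provided:

``kaiser``
    The classic procedure: successive pairwise planar rotations, each angle
    chosen in closed form to maximize the normal varimax criterion, swept
    until the criterion's relative change falls below tolerance.
``svd``
    The gradient-projection form used by R's ``stats::varimax``: compute the
    gradient of the varimax objective, take its singular value decomposition,
    set the rotation to U V', and iterate until the sum of singular values
    stabilizes.

Both are optionally preceded by Kaiser normalization (rows scaled to unit
communality before rotation and back-scaled after).

Promax then builds a target matrix by raising the varimax loadings
element-wise to a power k (sign preserved), optionally row-normalizing the
target first, and fits an oblique transformation to that target by least
squares. Programs differ in the varimax algorithm and in whether the target
is row-normalized; both choices, plus k, are settings here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import CollinearFactorsError, DegenerateInputError
from .paf import normalize_column_signs

_VARIMAX_TYPES = ("kaiser", "svd")
_P_TYPES = ("unnorm", "norm")


@dataclass(frozen=True)
class RotationSettings:
    """Configuration of the varimax + promax rotation stage.

    Attributes
    ----------
    varimax_type
        ``"kaiser"`` (pairwise planar rotations) or ``"svd"``
        (gradient/SVD projection).
    kaiser_normalize
        Scale loading rows to unit communality before varimax and back
        after (default True, the common convention).
    p_type
        Promax target construction: ``"unnorm"`` powers the varimax
        loadings directly (the original procedure), ``"norm"`` row-normalizes
        the target matrix first.
    k
        Promax power (default 4; 3 for unnormalized and 2 for normalized
        targets have been advocated as alternatives).
    rotate_tol, rotate_max_iter
        Varimax convergence control.
    """

    varimax_type: str = "kaiser"
    kaiser_normalize: bool = True
    p_type: str = "norm"
    k: int = 4
    rotate_tol: float = 1e-10
    rotate_max_iter: int = 1000

    def __post_init__(self):
        if self.varimax_type not in _VARIMAX_TYPES:
            raise ValueError(f"varimax_type must be one of {_VARIMAX_TYPES}")
        if self.p_type not in _P_TYPES:
            raise ValueError(f"p_type must be one of {_P_TYPES}")
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise ValueError("k must be a positive integer")
        if not self.rotate_tol > 0:
            raise ValueError("rotate_tol must be positive")
        if self.rotate_max_iter < 1:
            raise ValueError("rotate_max_iter must be at least 1")


@dataclass(frozen=True)
class RotatedSolution:
    """Varimax and promax output for one extraction."""

    varimax_loadings: np.ndarray
    rotation_matrix: np.ndarray
    pattern: np.ndarray
    structure: np.ndarray
    phi: np.ndarray
    transformation: np.ndarray
    settings_used: RotationSettings

    @property
    def p(self) -> int:
        return self.pattern.shape[0]

    @property
    def m(self) -> int:
        return self.pattern.shape[1]


def varimax_criterion(L: np.ndarray) -> float:
    """Normal varimax criterion: sum over factors of the variance of squared loadings."""
    p = L.shape[0]
    sq = L**2
    return float(np.sum(p * np.sum(sq**2, axis=0) - np.sum(sq, axis=0) ** 2) / p**2)


def _varimax_kaiser(L: np.ndarray, tol: float, max_iter: int, trace: list | None = None):
    p, m = L.shape
    L = L.copy()
    T = np.eye(m)
    crit = varimax_criterion(L)
    if trace is not None:
        trace.append(crit)
    for _ in range(max_iter):
        for i in range(m - 1):
            for j in range(i + 1, m):
                x, y = L[:, i], L[:, j]
                u = x * x - y * y
                v = 2.0 * x * y
                A = u.sum()
                B = v.sum()
                num = 2.0 * (np.dot(u, v) - A * B / p)
                den = np.dot(u, u) - np.dot(v, v) - (A * A - B * B) / p
                angle = 0.25 * np.arctan2(num, den)
                if abs(angle) < 1e-15:
                    continue
                c, s = np.cos(angle), np.sin(angle)
                rot = np.array([[c, -s], [s, c]])
                L[:, [i, j]] = L[:, [i, j]] @ rot
                T[:, [i, j]] = T[:, [i, j]] @ rot
        new = varimax_criterion(L)
        if trace is not None:
            trace.append(new)
        if new - crit < tol * max(1.0, abs(crit)):
            break
        crit = new
    return L, T


def _varimax_svd(L: np.ndarray, tol: float, max_iter: int):
    p, m = L.shape
    T = np.eye(m)
    d = 0.0
    for _ in range(max_iter):
        z = L @ T
        B = L.T @ (z**3 - z @ np.diag(np.sum(z**2, axis=0)) / p)
        U, s, Vt = np.linalg.svd(B)
        T = U @ Vt
        d_new = s.sum()
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    return L @ T, T


def varimax(
    loadings: np.ndarray,
    type: str = "kaiser",
    normalize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1000,
    criterion_trace: list | None = None,
):
    """Varimax-rotate a loading matrix.

    Returns ``(rotated, rotation)`` with ``rotated = loadings @ rotation``
    and ``rotation`` orthogonal. A single-factor input is returned unchanged
    with the 1 x 1 identity rotation.
    """
    L = np.asarray(loadings, dtype=float)
    p, m = L.shape
    if m == 1:
        return L.copy(), np.eye(1)
    if normalize:
        h = np.sqrt(np.sum(L**2, axis=1))
        if np.any(h == 0):
            raise DegenerateInputError(
                "Kaiser normalization undefined for a zero-communality row"
            )
        Lw = L / h[:, None]
    else:
        h = None
        Lw = L
    if type == "kaiser":
        Rw, T = _varimax_kaiser(Lw, tol, max_iter, trace=criterion_trace)
    elif type == "svd":
        Rw, T = _varimax_svd(Lw, tol, max_iter)
    else:
        raise ValueError(f"unknown varimax type {type!r}")
    rotated = Rw * h[:, None] if normalize else Rw
    # sign convention: largest-|loading| entry positive per column; flip the
    # rotation columns in lockstep so rotated == loadings @ rotation holds.
    for j in range(m):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] < 0:
            rotated[:, j] = -rotated[:, j]
            T[:, j] = -T[:, j]
    return rotated, T


def promax(
    varimax_loadings: np.ndarray,
    rotation: np.ndarray,
    settings: RotationSettings | None = None,
) -> RotatedSolution:
    """Oblique promax rotation of a varimax solution.

    Builds the power target from the varimax loadings (optionally
    row-normalized), fits the oblique transformation by least squares
    against the unnormalized varimax loadings, rescales it so the implied
    factors have unit variance, and returns pattern, structure and the
    factor intercorrelation matrix phi. For a single factor the oblique
    step is undefined and the varimax solution is passed through with
    phi = [[1]].
    """
    settings = settings or RotationSettings()
    A = np.asarray(varimax_loadings, dtype=float)
    p, m = A.shape
    if m == 1:
        return RotatedSolution(
            varimax_loadings=A.copy(),
            rotation_matrix=np.asarray(rotation, dtype=float).copy(),
            pattern=A.copy(),
            structure=A.copy(),
            phi=np.eye(1),
            transformation=np.eye(1),
            settings_used=settings,
        )
    if settings.p_type == "norm":
        norms = np.sqrt(np.sum(A**2, axis=1))
        safe = np.where(norms == 0, 1.0, norms)
        A_star = A / safe[:, None]
    else:
        A_star = A
    Q = np.sign(A_star) * np.abs(A_star) ** settings.k
    AtA = A.T @ A
    try:
        U = np.linalg.solve(AtA, A.T @ Q)
    except np.linalg.LinAlgError as exc:
        raise CollinearFactorsError("varimax loadings are collinear; cannot fit target") from exc
    try:
        UtU_inv = np.linalg.inv(U.T @ U)
    except np.linalg.LinAlgError as exc:
        raise CollinearFactorsError("oblique transformation is singular") from exc
    U = U * np.sqrt(np.diag(UtU_inv))[None, :]
    pattern = A @ U
    phi = np.linalg.inv(U.T @ U)
    d = 1.0 / np.sqrt(np.diag(phi))
    phi = phi * np.outer(d, d)
    phi = (phi + phi.T) / 2.0
    np.fill_diagonal(phi, 1.0)
    structure = pattern @ phi
    return RotatedSolution(
        varimax_loadings=A.copy(),
        rotation_matrix=np.asarray(rotation, dtype=float).copy(),
        pattern=pattern,
        structure=structure,
        phi=phi,
        transformation=U,
        settings_used=settings,
    )


def rotate(unrotated_loadings: np.ndarray, settings: RotationSettings | None = None) -> RotatedSolution:
    """Full rotation stage: varimax then promax under one settings object."""
    settings = settings or RotationSettings()
    vload, T = varimax(
        unrotated_loadings,
        type=settings.varimax_type,
        normalize=settings.kaiser_normalize,
        tol=settings.rotate_tol,
        max_iter=settings.rotate_max_iter,
    )
    return promax(vload, T, settings)


__all__ = [
    "RotationSettings",
    "RotatedSolution",
    "varimax",
    "varimax_criterion",
    "promax",
    "rotate",
    "normalize_column_signs",
]
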