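"""Half-space polytopes and their geometry.

A polytope is stored in H-representation, ``P = {x : A x <= b}``, with one
constraint per row of ``A``.  This module provides membership tests, chord
(line-segment) computation for hit-and-run kernels, the Chebyshev-center
feasibility check, redundancy removal, the null-space embedding that turns an
implicit polytope (inequalities plus an underdetermined equality system) into
an explicit full-dimensional one, and factories for the standard polytopes used
throughout the test suite (hypercubes, simplices, Birkhoff polytopes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg
from scipy.optimize import linprog

from .exceptions import (
    DegenerateError,
    DimensionError,
    FeasibilityError,
    InconsistentError,
    InfeasibleError,
    UnboundedError,
)

# Strict-interior margin: interior points must satisfy each constraint with
# slack >= INTERIOR_MARGIN * (1 + |b_i|).  Avoids zero-length chords at the
# boundary.
INTERIOR_MARGIN = 1e-12

#: Default tolerance for redundancy removal (above LP solver tolerance, below
#: meaningful constraint differences).
REDUNDANCY_TOL = 1e-9


def _as_matrix(A, name: str) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise DimensionError(f"{name} must be a 2-d matrix, got ndim={A.ndim}")
    if not np.all(np.isfinite(A)):
        raise ValueError(f"{name} contains non-finite entries")
    return A


def _as_vector(b, name: str) -> np.ndarray:
    b = np.asarray(b, dtype=float).reshape(-1)
    if not np.all(np.isfinite(b)):
        raise ValueError(f"{name} contains non-finite entries")
    return b


@dataclass(frozen=True)
class Polytope:
    """Convex polytope ``{x in R^n : A x <= b}`` in half-space form.

    ``A`` has one row per inequality (m_ineq x n); ``b`` has length m_ineq.
    """

    A: np.ndarray
    b: np.ndarray
    label: Optional[str] = None

    def __post_init__(self):
        A = _as_matrix(self.A, "A")
        b = _as_vector(self.b, "b")
        if A.shape[0] != b.shape[0]:
            raise DimensionError(
                f"A has {A.shape[0]} rows but b has {b.shape[0]} entries"
            )
        if A.shape[0] < 1 or A.shape[1] < 1:
            raise DimensionError("polytope needs at least one constraint and one dimension")
        zero_rows = ~np.any(A != 0.0, axis=1)
        if np.any(zero_rows & (b < 0)):
            raise InfeasibleError("all-zero constraint row with negative bound")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", b)

    @property
    def dim(self) -> int:
        return self.A.shape[1]

    @property
    def n_constraints(self) -> int:
        return self.A.shape[0]

    def __repr__(self):  # pragma: no cover - cosmetic
        lbl = f", label={self.label!r}" if self.label else ""
        return f"Polytope(m={self.n_constraints}, n={self.dim}{lbl})"


@dataclass(frozen=True)
class EqualitySystem:
    """Linear equality system ``S x = c`` (the implicit part of a polytope)."""

    S: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        S = _as_matrix(self.S, "S")
        c = _as_vector(self.c, "c")
        if S.shape[0] != c.shape[0]:
            raise DimensionError(
                f"S has {S.shape[0]} rows but c has {c.shape[0]} entries"
            )
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "c", c)

    @property
    def dim(self) -> int:
        return self.S.shape[1]


@dataclass(frozen=True)
class TransformRecord:
    """Invertible affine map ``full = basis @ reduced + shift``.

    Links a preprocessed (reduced and/or rounded) space to the original
    parameter space.  ``basis`` must have full column rank so the map is
    injective and invertible via the pseudo-inverse.
    """

    basis: np.ndarray
    shift: np.ndarray

    def __post_init__(self):
        basis = _as_matrix(self.basis, "basis")
        shift = _as_vector(self.shift, "shift")
        if basis.shape[0] != shift.shape[0]:
            raise DimensionError("basis rows and shift length differ")
        if np.linalg.matrix_rank(basis) < basis.shape[1]:
            raise ValueError("transform basis is column-rank deficient")
        object.__setattr__(self, "basis", basis)
        object.__setattr__(self, "shift", shift)

    @property
    def full_dim(self) -> int:
        return self.basis.shape[0]

    @property
    def reduced_dim(self) -> int:
        return self.basis.shape[1]

    def apply(self, reduced: np.ndarray) -> np.ndarray:
        """Map reduced-space point(s) to full space (points are rows if 2-d)."""
        reduced = np.asarray(reduced, dtype=float)
        if reduced.shape[-1] != self.reduced_dim:
            raise DimensionError(
                f"points have dimension {reduced.shape[-1]}, "
                f"transform expects {self.reduced_dim}"
            )
        return reduced @ self.basis.T + self.shift

    def invert(self, full: np.ndarray) -> np.ndarray:
        """Least-squares inverse: recover reduced point(s) from full space."""
        full = np.asarray(full, dtype=float)
        if full.shape[-1] != self.full_dim:
            raise DimensionError(
                f"points have dimension {full.shape[-1]}, "
                f"transform expects {self.full_dim}"
            )
        pinv = np.linalg.pinv(self.basis)
        return (full - self.shift) @ pinv.T

    def compose(self, inner: "TransformRecord") -> "TransformRecord":
        """Composition self∘inner: first apply ``inner``, then ``self``."""
        return TransformRecord(
            basis=self.basis @ inner.basis,
            shift=self.basis @ inner.shift + self.shift,
        )

    @staticmethod
    def identity(n: int) -> "TransformRecord":
        return TransformRecord(np.eye(n), np.zeros(n))


@dataclass(frozen=True)
class ChebyshevResult:
    """Center and radius of the largest ball inscribed in a polytope."""

    center: np.ndarray
    radius: float


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def contains(P: Polytope, point, tol: float = 0.0) -> bool:
    """True iff every inequality holds up to slack ``tol``."""
    point = _as_vector(point, "point")
    if point.shape[0] != P.dim:
        raise DimensionError(
            f"point has dimension {point.shape[0]}, polytope has {P.dim}"
        )
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    return bool(np.all(P.A @ point <= P.b + tol))


def is_strictly_interior(P: Polytope, point: np.ndarray) -> bool:
    """Interior test with the package-wide relative slack margin."""
    point = _as_vector(point, "point")
    if point.shape[0] != P.dim:
        raise DimensionError("point/polytope dimension mismatch")
    slack = P.b - P.A @ point
    return bool(np.all(slack >= INTERIOR_MARGIN * (1.0 + np.abs(P.b))))


def chord_bounds(P: Polytope, origin, direction) -> tuple[float, float]:
    """Maximal interval [lambda_min, lambda_max] with lambda_min < 0 < lambda_max
    such that ``origin + lam * direction`` stays in ``P``.

    For each row the candidate bound is ``(b_i - a_i.origin) / (a_i.direction)``,
    an upper bound when ``a_i.direction > 0`` and a lower bound when negative;
    rows orthogonal to the direction impose no bound.
    """
    origin = _as_vector(origin, "origin")
    direction = _as_vector(direction, "direction")
    if origin.shape[0] != P.dim or direction.shape[0] != P.dim:
        raise DimensionError("origin/direction dimension mismatch with polytope")
    if not np.any(direction != 0.0):
        raise ValueError("direction must be nonzero")
    slack = P.b - P.A @ origin
    if np.any(slack < INTERIOR_MARGIN * (1.0 + np.abs(P.b))):
        raise FeasibilityError("chord origin is not strictly interior")
    t = P.A @ direction
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = slack / t
    pos = t > 0.0
    neg = t < 0.0
    if not np.any(pos):
        raise UnboundedError(f"chord unbounded above along direction {direction}")
    if not np.any(neg):
        raise UnboundedError(f"chord unbounded below along direction {direction}")
    lam_max = float(np.min(ratios[pos]))
    lam_min = float(np.max(ratios[neg]))
    return lam_min, lam_max


def chebyshev_center(P: Polytope) -> ChebyshevResult:
    """Largest inscribed ball via the standard LP.

    maximize r  s.t.  a_i.x + r * ||a_i||_2 <= b_i,  r >= 0.

    A strictly positive radius certifies a nonempty interior; an infeasible LP
    means the polytope is empty, an unbounded LP that it is unbounded.  This is
    the package's feasibility check.
    """
    norms = np.linalg.norm(P.A, axis=1)
    n = P.dim
    A_ub = np.hstack([P.A, norms[:, None]])
    cost = np.zeros(n + 1)
    cost[-1] = -1.0  # maximize r
    bounds = [(None, None)] * n + [(0.0, None)]
    res = linprog(cost, A_ub=A_ub, b_ub=P.b, bounds=bounds, method="highs")
    if res.status == 2:
        raise InfeasibleError("polytope is empty (Chebyshev LP infeasible)")
    if res.status == 3:
        raise UnboundedError("polytope is unbounded (Chebyshev LP unbounded)")
    if not res.success:  # pragma: no cover - solver hiccup
        raise FeasibilityError(f"Chebyshev LP failed: {res.message}")
    center = res.x[:n]
    radius = float(res.x[-1])
    return ChebyshevResult(center=center, radius=radius)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def remove_redundant_constraints(P: Polytope, tol: float = REDUNDANCY_TOL) -> Polytope:
    """Drop constraints that never bind.

    Exact duplicates (after normalizing each row by its norm) are removed
    first; then, for each remaining row i, ``a_i.x`` is maximized over the
    polytope defined by all other retained rows and row i is dropped iff the
    optimum stays below ``b_i - tol``.  The feasible set is unchanged and the
    order of retained rows is preserved.
    """
    cheb = chebyshev_center(P)  # raises InfeasibleError on empty input
    if cheb.radius <= 0.0:
        raise FeasibilityError("redundancy removal requires a nonempty interior")

    A, b = P.A, P.b
    norms = np.linalg.norm(A, axis=1)
    norms[norms == 0.0] = 1.0
    keys = np.round(np.column_stack([A / norms[:, None], b / norms]), 12)
    _, first_idx = np.unique(keys, axis=0, return_index=True)
    keep = np.zeros(A.shape[0], dtype=bool)
    keep[first_idx] = True

    idx = [i for i in range(A.shape[0]) if keep[i]]
    retained = list(idx)
    for i in idx:
        others = [j for j in retained if j != i]
        if not others:
            continue
        # cap with the row's own bound + 1 so the test LP is never unbounded;
        # if the optimum hits the cap the row certainly binds.
        A_ub = np.vstack([A[others], A[i]])
        b_ub = np.concatenate([b[others], [b[i] + 1.0]])
        res = linprog(
            -A[i], A_ub=A_ub, b_ub=b_ub,
            bounds=[(None, None)] * P.dim, method="highs",
        )
        if res.success and -res.fun < b[i] - tol:
            retained.remove(i)
    return Polytope(A[retained], b[retained], label=P.label)


def embed_equalities(eq: EqualitySystem, P: Polytope) -> tuple[Polytope, TransformRecord]:
    """Eliminate ``S x = c`` by restriction to the affine solution set.

    Computes a particular solution ``x0`` and an orthonormal null-space basis
    ``N`` of ``S``; the reduced polytope is ``{z : (A N) z <= b - A x0}`` and
    the returned record maps reduced points back via ``x = N z + x0``.  The
    reduced dimension is ``n - rank(S)``.
    """
    if eq.dim != P.dim:
        raise DimensionError(
            f"equality system dimension {eq.dim} != polytope dimension {P.dim}"
        )
    x0, *_ = np.linalg.lstsq(eq.S, eq.c, rcond=None)
    resid = np.max(np.abs(eq.S @ x0 - eq.c)) if eq.c.size else 0.0
    if resid > 1e-8 * (1.0 + np.max(np.abs(eq.c), initial=0.0)):
        raise InconsistentError(
            f"equality system has no solution (residual {resid:.3e})"
        )
    N = scipy.linalg.null_space(eq.S)  # orthonormal columns, numerical-rank rule
    if N.shape[1] == 0:
        raise DegenerateError("equality system has full rank: support is a point")
    A_red = P.A @ N
    b_red = P.b - P.A @ x0
    # rows annihilated by the projection are constant: drop if satisfied,
    # infeasible otherwise
    row_norms = np.linalg.norm(A_red, axis=1)
    dead = row_norms < 1e-12
    if np.any(dead):
        if np.any(b_red[dead] < -1e-9):
            raise InfeasibleError(
                "an inequality is violated everywhere on the equality set"
            )
        A_red, b_red = A_red[~dead], b_red[~dead]
        if A_red.shape[0] == 0:
            raise DegenerateError("no inequalities remain after embedding")
    reduced = Polytope(A_red, b_red, label=P.label)
    return reduced, TransformRecord(basis=N, shift=x0)


# ---------------------------------------------------------------------------
# standard polytope factories
# ---------------------------------------------------------------------------

def hypercube(n: int) -> Polytope:
    """Unit hypercube ``[0, 1]^n`` as 2n inequality rows."""
    if n < 1:
        raise ValueError("n must be >= 1")
    eye = np.eye(n)
    A = np.vstack([eye, -eye])
    b = np.concatenate([np.ones(n), np.zeros(n)])
    return Polytope(A, b, label=f"hypercube({n})")


def simplex(n: int, as_equality: bool = False):
    """Standard simplex on ``n`` coordinates.

    By default returns the full-dimensional form
    ``{x in R^n : x_i >= 0, sum(x) <= 1}`` (n+1 rows).  With
    ``as_equality=True`` returns the probability-simplex form on ``n + 1``
    nonnegative coordinates together with the ``sum = 1`` equality system, for
    use with :func:`embed_equalities`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not as_equality:
        A = np.vstack([-np.eye(n), np.ones((1, n))])
        b = np.concatenate([np.zeros(n), [1.0]])
        return Polytope(A, b, label=f"simplex({n})")
    m = n + 1
    P = Polytope(-np.eye(m), np.zeros(m), label=f"simplex({n})+eq")
    eq = EqualitySystem(np.ones((1, m)), np.array([1.0]))
    return P, eq


def birkhoff(n: int) -> tuple[Polytope, TransformRecord]:
    """Birkhoff polytope of n x n doubly stochastic matrices, full-dimensional.

    Builds the n^2 nonnegativity constraints and the 2n row/column-sum
    equalities, then embeds the equalities; the reduced dimension is
    ``(n - 1)^2`` (the sum-constraint matrix has rank 2n - 1).  The record maps
    a reduced point back to the n^2 matrix entries in row-major order.
    """
    if n < 2:
        raise ValueError("birkhoff requires n >= 2")
    n2 = n * n
    P = Polytope(-np.eye(n2), np.zeros(n2), label=f"birkhoff({n})")
    S = np.zeros((2 * n, n2))
    for i in range(n):
        S[i, i * n:(i + 1) * n] = 1.0       # row sums
        S[n + i, i::n] = 1.0                # column sums
    eq = EqualitySystem(S, np.ones(2 * n))
    reduced, record = embed_equalities(eq, P)
    return reduced, record
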