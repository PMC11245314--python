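"""Polytope rounding.

An anisotropic polytope (think a long thin box) makes isotropic hit-and-run
directions waste almost every proposal on the short axes.  Rounding finds an
invertible affine reparametrization ``x = T z + s`` under which the polytope is
near-isotropic, so that sphere-uniform directions mix well; samples are mapped
back through the accompanying :class:`~chordwalk.polytope.TransformRecord`.

Two methods are shipped behind one interface:

``ellipsoid``
    Deterministic: iteratively recenters at the Chebyshev center and rescales
    by the inverse square root of the slack-weighted constraint Gram matrix
    ``H = sum_i a_i a_i^T / s_i^2`` (the Dikin ellipsoid shape at the center,
    which is always inscribed in the polytope).

``covariance_svd``
    Stochastic: alternates short uniform coordinate-hit-and-run pre-sampling
    with an SVD of the sample covariance, composing the transform with
    ``U Sigma^(1/2)`` until the covariance condition number stabilizes.

Both finish by translating the Chebyshev center to the origin and scaling so
the rounded polytope contains a unit ball centered there.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateError, DimensionError
from .polytope import (
    Polytope,
    TransformRecord,
    chebyshev_center,
    chord_bounds,
)

#: Stop early once inscribed-radius / max-axis-half-chord reaches this.
QUALITY_TARGET = 0.2

#: Coordinate hit-and-run pre-sampling budget per covariance_svd iteration,
#: in steps per dimension.
PRESAMPLE_STEPS_PER_DIM = 50

_COV_RIDGE = 1e-12  # relative diagonal regularization before SVD


def rounding_quality(P: Polytope) -> float:
    """Inscribed-ball radius over max axis half-chord through the center.

    A crude in/out ball-ratio proxy: 1 is perfectly round, small values mean
    strong anisotropy.  Axis chords from the Chebyshev center estimate the
    enclosing radius from 2n directions.
    """
    cheb = chebyshev_center(P)
    half = _max_axis_half_chord(P, cheb.center)
    return cheb.radius / half if half > 0 else 0.0


def _max_axis_half_chord(P: Polytope, center: np.ndarray) -> float:
    out = 0.0
    for j in range(P.dim):
        e = np.zeros(P.dim)
        e[j] = 1.0
        lo, hi = chord_bounds(P, center, e)
        out = max(out, hi, -lo)
    return out


def _chr_presample(P: Polytope, start: np.ndarray, n_steps: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Uniform coordinate hit-and-run walk used only inside rounding."""
    x = start.copy()
    out = np.empty((n_steps, P.dim))
    for k in range(n_steps):
        j = int(rng.integers(P.dim))
        e = np.zeros(P.dim)
        e[j] = 1.0
        lo, hi = chord_bounds(P, x, e)
        x = x.copy()
        x[j] += rng.uniform(lo, hi)
        out[k] = x
    return out


def _spd_inv_sqrt(H: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(H)
    w = np.clip(w, 1e-300, None)
    return (V / np.sqrt(w)) @ V.T


def _analytic_center(A: np.ndarray, b: np.ndarray, x0: np.ndarray,
                     max_newton: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Damped Newton minimization of -sum log(b - A x), started interior.

    Unlike the Chebyshev center the analytic center is unique, so it is a
    stable point at which to evaluate the Dikin-ellipsoid shape.
    """
    x = x0.copy()
    for _ in range(max_newton):
        s = b - A @ x
        g = A.T @ (1.0 / s)
        W = A / s[:, None]
        H = W.T @ W
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:  # pragma: no cover - near-singular H
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        decrement = g @ step
        t = 1.0
        while np.any(b - A @ (x - t * step) <= 0.0):
            t *= 0.5
            if t < 1e-12:
                return x
        x = x - t * step
        if decrement < tol:
            break
    return x


def round_polytope(
    P: Polytope,
    method: str = "ellipsoid",
    max_iter: int = 10,
    tol: float = 0.05,
    seed: int = 0,
) -> tuple[Polytope, TransformRecord]:
    """Round ``P`` and return the rounded polytope plus the transform record.

    The returned polytope ``P' = {z : (A T) z <= b - A s}`` contains a unit
    ball centered at the origin; ``TransformRecord(basis=T, shift=s)`` maps
    rounded-space samples back to the original space.  Iteration stops when
    the rounding quality reaches :data:`QUALITY_TARGET` (ellipsoid) or the
    covariance condition number changes by less than ``tol`` (covariance_svd),
    or after ``max_iter`` passes.
    """
    if method not in ("ellipsoid", "covariance_svd"):
        raise ValueError(f"unknown rounding method {method!r}")
    cheb = chebyshev_center(P)  # raises on empty/unbounded input
    if cheb.radius <= 0.0:
        raise DegenerateError("cannot round a polytope with empty interior")

    n = P.dim
    A = P.A.copy()
    b = P.b.copy()
    T = np.eye(n)
    s = np.zeros(n)

    def _recenter(analytic: bool = False):
        nonlocal A, b, s
        c = chebyshev_center(Polytope(A, b)).center
        if analytic:
            c = _analytic_center(A, b, c)
        s = s + T @ c
        b = b - A @ c
        return c

    if method == "ellipsoid":
        # quality is measured AFTER each Dikin step: the axis-chord enclosing
        # estimate is blind to rotated elongation, but one Dikin rescaling
        # aligns the axes with the body well enough for it to be meaningful
        # (and is near-identity on an already-round body).
        for _ in range(max_iter):
            _recenter(analytic=True)
            slack = b  # slacks at the (origin-shifted) analytic center
            W = A / slack[:, None]
            H = W.T @ W  # sum a_i a_i^T / s_i^2
            E = _spd_inv_sqrt(H)
            A = A @ E
            T = T @ E
            cur = Polytope(A, b)
            cheb = chebyshev_center(cur)
            if cheb.radius / _max_axis_half_chord(cur, cheb.center) \
                    >= QUALITY_TARGET:
                break
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        prev_cond = None
        for _ in range(max_iter):
            _recenter()
            cur = Polytope(A, b)
            start = chebyshev_center(cur).center
            draws = _chr_presample(cur, start, PRESAMPLE_STEPS_PER_DIM * n, rng)
            cov = np.cov(draws, rowvar=False)
            cov = np.atleast_2d(cov)
            cov = cov + (_COV_RIDGE * np.trace(cov) / n) * np.eye(n)
            w, U = np.linalg.eigh(cov)
            w = np.clip(w, 1e-300, None)
            cond = float(np.sqrt(w.max() / w.min()))
            E = U @ np.diag(np.sqrt(w)) @ U.T
            A = A @ E
            T = T @ E
            if prev_cond is not None and abs(cond - prev_cond) < tol * prev_cond:
                break
            prev_cond = cond

    # final normalization: center at origin, inscribed unit ball
    _recenter()
    r = chebyshev_center(Polytope(A, b)).radius
    A = A * r
    T = T * r
    rounded = Polytope(A, b, label=P.label)
    return rounded, TransformRecord(basis=T, shift=s)


def map_back(record: TransformRecord, samples: np.ndarray) -> np.ndarray:
    """Apply ``full = basis @ reduced + shift`` row-wise to ``samples``.

    Composable across stacked records (equality embedding then rounding):
    mapping through ``outer.compose(inner)`` equals mapping through ``inner``
    then ``outer``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.shape[-1] != record.reduced_dim:
        raise DimensionError(
            f"samples have dimension {samples.shape[-1]}, "
            f"record expects {record.reduced_dim}"
        )
    return record.apply(samples)
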