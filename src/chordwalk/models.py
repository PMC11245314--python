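"""Log-density models and the sampling Problem container.

A model is anything exposing ``log_density(x) -> float`` and, optionally,
``log_gradient(x)`` and a positive-definite ``log_curvature(x)``.  Densities
are understood up to an additive constant (Metropolis ratios cancel it), but
the built-ins include their normalization constants so they can be tested
against closed forms.  Returning ``-inf`` is legal (zero density); returning
NaN is always an error and is reported with the offending point.

The support restriction is never the model's job: the polytope handles it, so
e.g. the uniform model is simply the constant 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.linalg
from scipy.special import logsumexp

from .exceptions import ContractError, DimensionError, PluginError
from .polytope import Polytope, TransformRecord, is_strictly_interior


@dataclass(frozen=True)
class Model:
    """Log-density contract: value, optional gradient, optional curvature."""

    log_density: Callable[[np.ndarray], float]
    log_gradient: Optional[Callable[[np.ndarray], np.ndarray]] = None
    log_curvature: Optional[Callable[[np.ndarray], np.ndarray]] = None
    #: True only for the flat target; lets uniform-only kernels verify their
    #: precondition.
    is_uniform: bool = False


def uniform_model() -> Model:
    """Flat target: log-density 0 everywhere, zero gradient."""
    return Model(
        log_density=lambda x: 0.0,
        log_gradient=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        is_uniform=True,
    )


def gaussian_model(mean, covariance) -> Model:
    """Multivariate normal with full normalization constant.

    log f(x) = -1/2 (x-mu)^T Sigma^-1 (x-mu) - 1/2 log det(2 pi Sigma)
    gradient  = -Sigma^-1 (x-mu),  curvature = Sigma^-1 (constant, SPD).
    """
    mu = np.asarray(mean, dtype=float).reshape(-1)
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    if cov.shape != (mu.size, mu.size):
        raise DimensionError("covariance shape does not match mean length")
    if not np.allclose(cov, cov.T, atol=1e-12):
        raise ValueError("covariance must be symmetric")
    try:
        cho = scipy.linalg.cho_factor(cov, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive-definite") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    const = -0.5 * (mu.size * np.log(2.0 * np.pi) + logdet)
    prec = scipy.linalg.cho_solve(cho, np.eye(mu.size))

    def log_density(x):
        d = np.asarray(x, dtype=float) - mu
        return float(const - 0.5 * d @ scipy.linalg.cho_solve(cho, d))

    def log_gradient(x):
        d = np.asarray(x, dtype=float) - mu
        return -scipy.linalg.cho_solve(cho, d)

    return Model(
        log_density=log_density,
        log_gradient=log_gradient,
        log_curvature=lambda x: prec,
    )


def mixture_model(components: Sequence[Model], weights: Sequence[float]) -> Model:
    """Finite mixture: log-sum-exp over {log w_k + log f_k(x)}.

    Weights need only be positive; they are normalized internally.  Evaluation
    is numerically stable (max subtraction inside logsumexp).
    """
    components = list(components)
    if not components:
        raise ValueError("mixture needs at least one component")
    w = np.asarray(weights, dtype=float).reshape(-1)
    if w.size != len(components) or np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive, finite, one per component")
    logw = np.log(w / w.sum())

    def log_density(x):
        vals = np.array([m.log_density(x) for m in components]) + logw
        return float(logsumexp(vals))

    return Model(log_density=log_density)


def wrap_plugin(user_object, probe: Optional[np.ndarray] = None) -> Model:
    """Adapt a user object with a ``log_density`` callable to the Model contract.

    ``log_gradient``/``log_curvature`` attributes are picked up when present.
    If ``probe`` (a strictly interior point) is given, the log-density is
    evaluated there at wrap time and a NaN return is rejected immediately;
    at sampling time any NaN raises a :class:`PluginError` naming the point.
    """
    fn = getattr(user_object, "log_density", None)
    if not callable(fn):
        raise ContractError("plugin object must expose a callable 'log_density'")

    def log_density(x):
        v = float(fn(x))
        if np.isnan(v):
            raise PluginError(f"plugin log_density returned NaN at point {np.asarray(x)}")
        return v

    if probe is not None:
        v = float(fn(np.asarray(probe, dtype=float)))
        if np.isnan(v):
            raise ContractError(f"plugin log_density returned NaN at probe point {probe}")

    grad = getattr(user_object, "log_gradient", None)
    curv = getattr(user_object, "log_curvature", None)
    return Model(
        log_density=log_density,
        log_gradient=grad if callable(grad) else None,
        log_curvature=curv if callable(curv) else None,
    )


@dataclass(frozen=True)
class Problem:
    """A sampling target: polytope support, model, optional transform.

    ``polytope`` lives in the sampling (reduced/rounded) space where proposals
    operate; ``transform`` maps sampling-space points to the original
    parameter space, and the model is always evaluated in ORIGINAL
    coordinates.  With ``transform=None`` the two spaces coincide.
    """

    polytope: Polytope
    model: Model
    transform: Optional[TransformRecord] = None

    def __post_init__(self):
        if self.transform is not None and self.transform.reduced_dim != self.polytope.dim:
            raise DimensionError(
                f"transform reduced dimension {self.transform.reduced_dim} != "
                f"polytope dimension {self.polytope.dim}"
            )

    @property
    def dim(self) -> int:
        """Dimension of the sampling space."""
        return self.polytope.dim

    def to_original(self, points: np.ndarray) -> np.ndarray:
        """Map sampling-space point(s) to original coordinates."""
        if self.transform is None:
            return np.asarray(points, dtype=float)
        return self.transform.apply(points)

    def log_density(self, z: np.ndarray) -> float:
        """Model log-density at the original-space image of ``z``."""
        v = float(self.model.log_density(self.to_original(z)))
        if np.isnan(v):
            raise PluginError(f"model log_density returned NaN at point {np.asarray(z)}")
        return v

    def require_interior(self, point: np.ndarray) -> None:
        if not is_strictly_interior(self.polytope, point):
            from .exceptions import FeasibilityError

            raise FeasibilityError("starting point is not strictly interior")
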