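"""Proposal marketplace.

Every transition kernel satisfies one minimal contract: it holds the current
``state`` (a point in sampling-space coordinates), builds a candidate with
``propose(rng)`` WITHOUT mutating the state, reports a
``log_acceptance_correction`` (log ratio of reverse to forward proposal
densities; 0 for symmetric kernels), and is moved by the engine via
``move_to`` once the Metropolis filter accepts.  Kernels that expose a
``step_size`` attribute are tunable.

All shipped kernels are chord-based hit-and-run variants, so candidates are
polytope members by construction.  Third-party kernels register through
:func:`register_proposal` and then work with every engine feature.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from typing import Callable, Dict

import numpy as np

from .exceptions import RegistryError, UnsupportedTargetError
from .models import Problem
from .polytope import chord_bounds

_DIRECTION_EPS = 1e-300  # redraw directions shorter than this
_SQRT2 = math.sqrt(2.0)


class Proposal(ABC):
    """Minimal transition-kernel contract (see module docstring)."""

    #: subclasses that are tunable set this to a positive float
    step_size: float | None = None

    def __init__(self, problem: Problem, start: np.ndarray):
        start = np.asarray(start, dtype=float).reshape(-1)
        problem.require_interior(start)
        self.problem = problem
        self._state = start.copy()

    @property
    def state(self) -> np.ndarray:
        """Current point (copy: callers cannot mutate the kernel)."""
        return self._state.copy()

    def move_to(self, point: np.ndarray) -> None:
        """Engine hook: commit an accepted candidate."""
        self._state = np.asarray(point, dtype=float).copy()

    @abstractmethod
    def propose(self, rng: np.random.Generator) -> np.ndarray:
        """Draw a candidate from the current state; never mutates it."""

    def log_acceptance_correction(self) -> float:
        """log q(reverse) - log q(forward); 0 for symmetric kernels."""
        return 0.0

    # -- checkpointing hooks -------------------------------------------------
    def get_internal_state(self) -> dict:
        """Serializable kernel internals beyond the current point."""
        return {}

    def set_internal_state(self, internal: dict) -> None:
        pass

    def init_params(self) -> dict:
        """Constructor parameters needed to rebuild this kernel."""
        return {}

    def _sphere_direction(self, rng: np.random.Generator) -> np.ndarray:
        while True:
            z = rng.standard_normal(self.problem.dim)
            norm = np.linalg.norm(z)
            if norm > _DIRECTION_EPS:
                return z / norm


class HitAndRunUniform(Proposal):
    """Hit-and-Run: sphere-uniform direction, uniform draw on the chord.

    The chord through x and the candidate x' is the same segment seen from
    either endpoint, so the chord-uniform draw is its own reverse and the
    Metropolis correction is 0 for any target (standard Hit-and-Run within
    Metropolis: the acceptance ratio reduces to the density ratio).
    """

    def propose(self, rng):
        d = self._sphere_direction(rng)
        lo, hi = chord_bounds(self.problem.polytope, self._state, d)
        return self._state + rng.uniform(lo, hi) * d


class CoordinateHitAndRun(Proposal):
    """Hit-and-Run restricted to uniformly chosen coordinate axes.

    On a rounded polytope and combined with engine-level thinning this is the
    coordinate-hit-and-run-with-rounding-and-thinning (CHRRT) scheme.
    """

    def propose(self, rng):
        j = int(rng.integers(self.problem.dim))
        d = np.zeros(self.problem.dim)
        d[j] = 1.0
        lo, hi = chord_bounds(self.problem.polytope, self._state, d)
        candidate = self._state.copy()
        candidate[j] += rng.uniform(lo, hi)
        return candidate


class GaussianHitAndRun(Proposal):
    """Hit-and-Run with a centered normal step along the chord.

    lambda ~ N(0, step_size^2), truncated to the chord by rejection (at most
    100 tries, then the kernel proposes to stay put and counts the event in
    ``stuck_count``).

    The kernel is NOT symmetric: the chord through x and x' is the same
    segment, but the truncation normalizer Z(y) = Phi(hi_y/s) - Phi(lo_y/s)
    depends on where y sits on it.  Ignoring this visibly under-disperses
    draws near the boundary, so the exact Metropolis correction
    ``log Z(x) - log Z(x')`` is reported for each proposal (the normal kernel
    itself cancels since phi(lambda/s) = phi(-lambda/s)).
    """

    _MAX_TRIES = 100

    def __init__(self, problem, start, step_size: float):
        super().__init__(problem, start)
        if not (step_size > 0):
            raise ValueError("step_size must be positive")
        self.step_size = float(step_size)
        self.stuck_count = 0
        self._last_correction = 0.0

    @staticmethod
    def _truncation_mass(lo: float, hi: float, s: float) -> float:
        inv = 1.0 / (s * _SQRT2)
        return 0.5 * (math.erf(hi * inv) - math.erf(lo * inv))

    def propose(self, rng):
        d = self._sphere_direction(rng)
        lo, hi = chord_bounds(self.problem.polytope, self._state, d)
        s = self.step_size
        for _ in range(self._MAX_TRIES):
            lam = rng.standard_normal() * s
            if lo < lam < hi:
                # seen from the candidate, the same chord spans
                # [lo - lam, hi - lam]
                z_fwd = self._truncation_mass(lo, hi, s)
                z_rev = self._truncation_mass(lo - lam, hi - lam, s)
                self._last_correction = math.log(z_fwd) - math.log(z_rev)
                return self._state + lam * d
        self.stuck_count += 1
        self._last_correction = 0.0
        return self._state.copy()

    def log_acceptance_correction(self) -> float:
        return self._last_correction

    def get_internal_state(self):
        return {"stuck_count": self.stuck_count,
                "last_correction": self._last_correction}

    def set_internal_state(self, internal):
        self.stuck_count = int(internal.get("stuck_count", 0))
        self._last_correction = float(internal.get("last_correction", 0.0))

    def init_params(self):
        return {"step_size": self.step_size}


class OverRelaxedHitAndRun(Proposal):
    """Over-relaxed Hit-and-Run: deterministic reflection through the chord
    midpoint.

    With chord [lo, hi] around the current point (lambda = 0), the candidate
    is at lambda' = lo + hi.  The move is self-inverse along the chord and
    preserves the uniform law (unit Jacobian), inducing antithetic (negatively
    correlated) moves.  Valid for the uniform target only, which is enforced
    at construction.
    """

    def __init__(self, problem, start):
        if not problem.model.is_uniform:
            raise UnsupportedTargetError(
                "over-relaxed hit-and-run is only valid for the uniform target"
            )
        super().__init__(problem, start)

    def propose(self, rng):
        d = self._sphere_direction(rng)
        lo, hi = chord_bounds(self.problem.polytope, self._state, d)
        return self._state + (lo + hi) * d


class AdaptiveSVDProposal(Proposal):
    """Hit-and-Run with directions shaped by the running sample covariance.

    Keeps a running mean/covariance of visited states; every
    ``update_interval`` steps (while fewer than ``adaptation_horizon`` total
    steps have been taken) it recomputes ``U Sigma U^T`` of the regularized
    covariance and thereafter draws directions as normalized
    ``U Sigma^(1/2) z`` with z standard normal.  After the horizon the shape
    is FROZEN, so the kernel is a fixed, valid Hit-and-Run from then on;
    pre-freeze draws should be treated as burn-in (the engine reports the
    freeze point via ``burn_in_steps``).
    """

    def __init__(self, problem, start, update_interval: int = 100,
                 adaptation_horizon: int = 2000):
        super().__init__(problem, start)
        if update_interval <= 0 or adaptation_horizon <= 0:
            raise ValueError("update_interval and adaptation_horizon must be positive")
        self.update_interval = int(update_interval)
        self.adaptation_horizon = int(adaptation_horizon)
        n = problem.dim
        self._count = 0
        self._mean = np.zeros(n)
        self._m2 = np.zeros((n, n))
        self._shape = np.eye(n)
        self._steps = 0

    @property
    def burn_in_steps(self) -> int:
        return self.adaptation_horizon

    def _observe(self, x):
        self._count += 1
        delta = x - self._mean
        self._mean += delta / self._count
        self._m2 += np.outer(delta, x - self._mean)

    def _refresh_shape(self):
        n = self.problem.dim
        if self._count < 2:
            self._shape = np.eye(n)  # degenerate startup: isotropic fallback
            return
        cov = self._m2 / (self._count - 1)
        cov = cov + (1e-12 * np.trace(cov) / n) * np.eye(n)
        w, U = np.linalg.eigh(cov)
        w = np.clip(w, 1e-300, None)
        self._shape = U @ np.diag(np.sqrt(w)) @ U.T

    def propose(self, rng):
        self._observe(self._state)
        self._steps += 1
        if self._steps <= self.adaptation_horizon and \
                self._steps % self.update_interval == 0:
            self._refresh_shape()
        while True:
            z = rng.standard_normal(self.problem.dim)
            d = self._shape @ z
            norm = np.linalg.norm(d)
            if norm > _DIRECTION_EPS:
                d /= norm
                break
        lo, hi = chord_bounds(self.problem.polytope, self._state, d)
        return self._state + rng.uniform(lo, hi) * d

    def get_internal_state(self):
        return {
            "count": self._count,
            "mean": self._mean.copy(),
            "m2": self._m2.copy(),
            "shape": self._shape.copy(),
            "steps": self._steps,
        }

    def set_internal_state(self, internal):
        self._count = int(internal["count"])
        self._mean = np.asarray(internal["mean"], dtype=float).copy()
        self._m2 = np.asarray(internal["m2"], dtype=float).copy()
        self._shape = np.asarray(internal["shape"], dtype=float).copy()
        self._steps = int(internal["steps"])

    def init_params(self):
        return {
            "update_interval": self.update_interval,
            "adaptation_horizon": self.adaptation_horizon,
        }


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_REGISTRY: Dict[str, Callable[..., Proposal]] = {}


def register_proposal(name: str, factory: Callable[..., Proposal]) -> None:
    """Register a kernel factory ``factory(problem, start, **params)``."""
    _REGISTRY[name] = factory


def proposal_names() -> list[str]:
    return sorted(_REGISTRY)


def make_proposal(name: str, problem: Problem, start, **params) -> Proposal:
    """Instantiate a registered kernel by name."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise RegistryError(
            f"unknown proposal {name!r}; valid names: {', '.join(proposal_names())}"
        ) from None
    return factory(problem, start, **params)


register_proposal("hit_and_run_uniform", HitAndRunUniform)
register_proposal("coordinate_hit_and_run", CoordinateHitAndRun)
register_proposal("gaussian_hit_and_run", GaussianHitAndRun)
register_proposal("over_relaxed_hit_and_run", OverRelaxedHitAndRun)
register_proposal("adaptive_svd", AdaptiveSVDProposal)


def hit_and_run_uniform(problem, start) -> HitAndRunUniform:
    return HitAndRunUniform(problem, start)


def coordinate_hit_and_run(problem, start) -> CoordinateHitAndRun:
    return CoordinateHitAndRun(problem, start)


def gaussian_hit_and_run(problem, start, step_size) -> GaussianHitAndRun:
    return GaussianHitAndRun(problem, start, step_size)


def over_relaxed_hit_and_run(problem, start) -> OverRelaxedHitAndRun:
    return OverRelaxedHitAndRun(problem, start)


def adaptive_svd_proposal(problem, start, update_interval=100,
                          adaptation_horizon=2000) -> AdaptiveSVDProposal:
    return AdaptiveSVDProposal(problem, start, update_interval, adaptation_horizon)
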