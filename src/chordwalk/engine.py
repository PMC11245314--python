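"""Sampling engine: Metropolis filtering, chains, tuning, tempering,
checkpointing.

Randomness comes from numpy's PCG64 bit generator — a 64-bit permuted
congruential generator with 128-bit state and period 2^128.  Each chain owns
an independent stream derived from ``(seed, stream_id)`` via SeedSequence
spawning, so results are a pure function of the seed regardless of how chains
are scheduled.

Chains never leave the polytope: proposals are chord-based and the Metropolis
filter additionally rejects any candidate failing membership (tol 1e-9)
without evaluating the model.  The cold target may be tempered: a chain at
temperature T targets f/T on the SAME support, so the hottest chain of a
parallel-tempering ladder still explores only the polytope.
"""

from __future__ import annotations

import hashlib
import math
import pickle
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import (
    CheckpointError,
    FeasibilityError,
    NotTunableError,
)
from .models import Problem
from .polytope import chebyshev_center, contains
from .proposals import Proposal, make_proposal

MEMBERSHIP_TOL = 1e-9

#: fraction of the inscribed radius used to jitter default per-chain starts
START_JITTER_FRACTION = 0.1

_CHECKPOINT_MAGIC = b"CWCKPT1\n"
_CHECKPOINT_SCHEMA = "chordwalk-chain-state-v1"


def make_rng(seed: int, stream_id: int = 0) -> np.random.Generator:
    """Independent PCG64 stream ``stream_id`` derived from ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(stream_id),))
    return np.random.Generator(np.random.PCG64(ss))


@dataclass
class ChainState:
    """Serializable snapshot of a chain: the unit of checkpointing."""

    position: np.ndarray
    log_density_cached: float
    proposal_config: dict          # {"name", "params", "internal"}
    rng_state: dict                # PCG64 bit-generator state
    step_count: int
    temperature: float = 1.0
    accept_count: int = 0
    seed: int = 0
    stream_id: int = 0


@dataclass
class SampleBatch:
    """Draws in ORIGINAL coordinates, shaped (chains, iterations, dim)."""

    draws: np.ndarray
    acceptance_rates: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_samples(self) -> int:
        return self.draws.shape[1]

    @property
    def dim(self) -> int:
        return self.draws.shape[2]


class MarkovChain:
    """One Metropolis–Hastings chain over a :class:`Problem`.

    The chain caches the UNtempered log-density of its current position; the
    accept test divides the density difference by the chain temperature.
    """

    def __init__(
        self,
        problem: Problem,
        proposal_name: str,
        seed: int = 0,
        stream_id: int = 0,
        start: Optional[np.ndarray] = None,
        temperature: float = 1.0,
        proposal_params: Optional[dict] = None,
    ):
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        self.problem = problem
        self.proposal_name = proposal_name
        self.seed = int(seed)
        self.stream_id = int(stream_id)
        self.temperature = float(temperature)
        self.rng = make_rng(seed, stream_id)
        if start is None:
            start = _default_start(problem, self.rng)
        start = np.asarray(start, dtype=float).reshape(-1)
        problem.require_interior(start)
        params = dict(proposal_params or {})
        if proposal_name == "gaussian_hit_and_run" and "step_size" not in params:
            # scale-aware default: the inscribed-ball radius of the support
            params["step_size"] = chebyshev_center(problem.polytope).radius
        self.proposal: Proposal = make_proposal(proposal_name, problem, start, **params)
        self._logf = problem.log_density(start)
        self.step_count = 0
        self.accept_count = 0

    # -- stepping ------------------------------------------------------------
    def step(self) -> bool:
        """One Metropolis–Hastings transition; returns True on acceptance."""
        candidate = self.proposal.propose(self.rng)
        self.step_count += 1
        P = self.problem.polytope
        if not np.all(P.A @ candidate <= P.b + MEMBERSHIP_TOL):
            return False  # support violation: reject without model evaluation
        logf_new = self.problem.log_density(candidate)
        log_alpha = (logf_new - self._logf) / self.temperature \
            + self.proposal.log_acceptance_correction()
        if log_alpha >= 0.0 or np.log(self.rng.uniform()) < log_alpha:
            self.proposal.move_to(candidate)
            self._logf = logf_new
            self.accept_count += 1
            return True
        return False

    def advance(self, n_steps: int) -> None:
        for _ in range(n_steps):
            self.step()

    def run(self, n_samples: int, thinning: int = 1) -> np.ndarray:
        """Record every ``thinning``-th state, in sampling-space coordinates."""
        if n_samples < 1 or thinning < 1:
            raise ValueError("n_samples and thinning must be positive")
        out = np.empty((n_samples, self.problem.dim))
        for k in range(n_samples):
            self.advance(thinning)
            out[k] = self.proposal.state
        return out

    # -- introspection -------------------------------------------------------
    @property
    def position(self) -> np.ndarray:
        return self.proposal.state

    @property
    def log_density(self) -> float:
        """Cached untempered log-density at the current position."""
        return self._logf

    @property
    def acceptance_rate(self) -> float:
        return self.accept_count / self.step_count if self.step_count else 0.0

    def exchange_with(self, other: "MarkovChain") -> None:
        """Swap positions (and cached densities) with another chain."""
        mine, theirs = self.position, other.position
        self.proposal.move_to(theirs)
        other.proposal.move_to(mine)
        self._logf, other._logf = other._logf, self._logf

    # -- checkpointing -------------------------------------------------------
    def state(self) -> ChainState:
        return ChainState(
            position=self.position,
            log_density_cached=self._logf,
            proposal_config={
                "name": self.proposal_name,
                "params": self.proposal.init_params(),
                "internal": self.proposal.get_internal_state(),
            },
            rng_state=self.rng.bit_generator.state,
            step_count=self.step_count,
            temperature=self.temperature,
            accept_count=self.accept_count,
            seed=self.seed,
            stream_id=self.stream_id,
        )

    @classmethod
    def from_state(cls, problem: Problem, state: ChainState) -> "MarkovChain":
        chain = cls.__new__(cls)
        chain.problem = problem
        chain.proposal_name = state.proposal_config["name"]
        chain.seed = state.seed
        chain.stream_id = state.stream_id
        chain.temperature = state.temperature
        chain.rng = make_rng(state.seed, state.stream_id)
        chain.rng.bit_generator.state = state.rng_state
        chain.proposal = make_proposal(
            chain.proposal_name, problem, state.position,
            **state.proposal_config["params"],
        )
        chain.proposal.set_internal_state(state.proposal_config["internal"])
        logf = problem.log_density(np.asarray(state.position, dtype=float))
        if abs(logf - state.log_density_cached) > 1e-12 * (1.0 + abs(logf)):
            raise CheckpointError(
                "cached log-density does not match re-evaluation on restore "
                f"({state.log_density_cached!r} vs {logf!r})"
            )
        chain._logf = logf
        chain.step_count = state.step_count
        chain.accept_count = state.accept_count
        return chain


def _default_start(problem: Problem, rng: np.random.Generator) -> np.ndarray:
    """Chebyshev center jittered uniformly within 0.1x the inscribed ball."""
    cheb = chebyshev_center(problem.polytope)
    if cheb.radius <= 0.0:
        raise FeasibilityError("polytope has empty interior: no valid start")
    n = problem.dim
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    r = rng.uniform() ** (1.0 / n)
    return cheb.center + START_JITTER_FRACTION * cheb.radius * r * v


def metropolis_step(state: ChainState, proposal: Proposal, problem: Problem,
                    rng: np.random.Generator) -> ChainState:
    """Functional single-step interface over :meth:`MarkovChain.step`.

    Candidates outside the polytope (tol 1e-9) are rejected without a model
    evaluation; otherwise accept with log alpha = min(0, (f' - f)/T + corr).
    The returned state has its step count advanced whether or not the move
    was accepted.
    """
    candidate = proposal.propose(rng)
    P = problem.polytope
    position = np.asarray(state.position, dtype=float)
    logf = state.log_density_cached
    accepted = False
    if np.all(P.A @ candidate <= P.b + MEMBERSHIP_TOL):
        logf_new = problem.log_density(candidate)
        log_alpha = (logf_new - logf) / state.temperature \
            + proposal.log_acceptance_correction()
        if log_alpha >= 0.0 or np.log(rng.uniform()) < log_alpha:
            proposal.move_to(candidate)
            position, logf = candidate, logf_new
            accepted = True
    return ChainState(
        position=position,
        log_density_cached=logf,
        proposal_config={
            "name": type(proposal).__name__,
            "params": proposal.init_params(),
            "internal": proposal.get_internal_state(),
        },
        rng_state=rng.bit_generator.state,
        step_count=state.step_count + 1,
        temperature=state.temperature,
        accept_count=state.accept_count + int(accepted),
        seed=state.seed,
        stream_id=state.stream_id,
    )


# ---------------------------------------------------------------------------
# multi-chain driver
# ---------------------------------------------------------------------------

def sample(
    problem: Problem,
    proposal_name: str,
    n_chains: int = 4,
    n_samples: int = 1000,
    thinning: int = 1,
    seed: int = 0,
    starts: Optional[Sequence[np.ndarray]] = None,
    proposal_params: Optional[dict] = None,
    discard_burn_in: bool = False,
) -> SampleBatch:
    """Run ``n_chains`` independent chains and collect original-space draws.

    Each chain gets its own RNG stream ``(seed, chain_index)``; identical
    inputs give bit-identical outputs.  Default starts are the Chebyshev
    center jittered within 0.1x the inscribed ball, per chain.  Every
    ``thinning``-th state is recorded, so each chain takes
    ``n_samples * thinning`` transitions.  Adaptive kernels report their
    freeze point in ``meta['burn_in_draws']``; draws are only dropped when
    ``discard_burn_in`` is set.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be positive")
    cheb = chebyshev_center(problem.polytope)  # feasibility check up front
    if cheb.radius <= 0.0:
        raise FeasibilityError("polytope has empty interior")
    if starts is not None and len(starts) != n_chains:
        raise ValueError("starts must supply one point per chain")

    chains = []
    for c in range(n_chains):
        start = None if starts is None else starts[c]
        chains.append(MarkovChain(
            problem, proposal_name, seed=seed, stream_id=c,
            start=start, proposal_params=proposal_params,
        ))

    draws = np.empty((n_chains, n_samples, _full_dim(problem)))
    rates = np.empty(n_chains)
    for c, chain in enumerate(chains):
        reduced = chain.run(n_samples, thinning)
        draws[c] = problem.to_original(reduced)
        rates[c] = chain.acceptance_rate

    burn_steps = getattr(chains[0].proposal, "burn_in_steps", 0)
    burn_draws = min(n_samples, math.ceil(burn_steps / thinning)) if burn_steps else 0
    meta = {
        "seed": int(seed),
        "proposal": proposal_name,
        "proposal_params": dict(proposal_params or {}),
        "thinning": int(thinning),
        "n_chains": int(n_chains),
        "polytope_label": problem.polytope.label,
        "burn_in_draws": int(burn_draws),
    }
    if discard_burn_in and burn_draws:
        draws = draws[:, burn_draws:, :]
    return SampleBatch(draws=draws, acceptance_rates=rates, meta=meta)


def _full_dim(problem: Problem) -> int:
    return problem.transform.full_dim if problem.transform is not None else problem.dim


# ---------------------------------------------------------------------------
# acceptance-rate tuning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TuneResult:
    step_size: float
    achieved_rate: float


def tune_acceptance_rate(
    problem: Problem,
    proposal_name: str,
    target_rate: float = 0.234,
    n_tuning: int = 5000,
    seed: int = 0,
    proposal_params: Optional[dict] = None,
    batch_size: int = 100,
) -> TuneResult:
    """Robbins–Monro tuning of a kernel's step size.

    After each batch of ``batch_size`` steps the log step size moves by
    ``gamma_k * (empirical rate - target_rate)`` with ``gamma_k = 2/(k+1)``.
    Returns the final step size and the rate achieved over the last batch.
    """
    if not (0.0 < target_rate < 1.0):
        raise ValueError("target_rate must lie strictly between 0 and 1")
    chain = MarkovChain(problem, proposal_name, seed=seed,
                        proposal_params=proposal_params)
    if chain.proposal.step_size is None:
        raise NotTunableError(
            f"proposal {proposal_name!r} exposes no step_size to tune"
        )
    n_batches = max(1, n_tuning // batch_size)
    rate = 0.0
    for k in range(1, n_batches + 1):
        before = chain.accept_count
        chain.advance(batch_size)
        rate = (chain.accept_count - before) / batch_size
        gamma = 2.0 / (k + 1.0)
        chain.proposal.step_size = float(
            np.exp(np.log(chain.proposal.step_size) + gamma * (rate - target_rate))
        )
    return TuneResult(step_size=chain.proposal.step_size, achieved_rate=rate)


# ---------------------------------------------------------------------------
# parallel tempering
# ---------------------------------------------------------------------------

@dataclass
class SwapStatistics:
    """Per-adjacent-pair replica-exchange bookkeeping."""

    attempts: np.ndarray
    accepts: np.ndarray

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.attempts > 0, self.accepts / self.attempts, np.nan)


def parallel_tempering(
    problem: Problem,
    proposal_name: str,
    temperatures: Sequence[float],
    n_samples: int = 1000,
    swap_interval: int = 10,
    seed: int = 0,
    thinning: int = 1,
    proposal_params: Optional[dict] = None,
) -> tuple[SampleBatch, SwapStatistics]:
    """Replica exchange over a temperature ladder, cold chain returned.

    Chain k targets ``f / T_k`` on the same polytope (the support is never
    tempered).  Every ``swap_interval`` sweeps, adjacent pairs — alternating
    even and odd pairings — propose a state exchange accepted with
    ``log alpha = (1/T_i - 1/T_j) * (f(theta_j) - f(theta_i))``.
    """
    temps = [float(t) for t in temperatures]
    if not temps or temps[0] != 1.0:
        raise ValueError("temperature ladder must start at 1")
    if any(b < a for a, b in zip(temps, temps[1:])):
        raise ValueError("temperature ladder must be non-decreasing")
    if swap_interval < 1:
        raise ValueError("swap_interval must be positive")
    K = len(temps)
    chains = [
        MarkovChain(problem, proposal_name, seed=seed, stream_id=k,
                    temperature=T, proposal_params=proposal_params)
        for k, T in enumerate(temps)
    ]
    swap_rng = make_rng(seed, K)
    attempts = np.zeros(max(K - 1, 1), dtype=int)
    accepts = np.zeros(max(K - 1, 1), dtype=int)

    cold = np.empty((1, n_samples, _full_dim(problem)))
    total_sweeps = 0
    swap_round = 0
    for k in range(n_samples):
        for _ in range(thinning):
            for chain in chains:
                chain.step()
            total_sweeps += 1
            if K > 1 and total_sweeps % swap_interval == 0:
                parity = swap_round % 2
                swap_round += 1
                for i in range(parity, K - 1, 2):
                    attempts[i] += 1
                    ci, cj = chains[i], chains[i + 1]
                    log_alpha = (1.0 / ci.temperature - 1.0 / cj.temperature) \
                        * (cj.log_density - ci.log_density)
                    if log_alpha >= 0.0 or np.log(swap_rng.uniform()) < log_alpha:
                        ci.exchange_with(cj)
                        accepts[i] += 1
        cold[0, k] = problem.to_original(chains[0].position)

    batch = SampleBatch(
        draws=cold,
        acceptance_rates=np.array([chains[0].acceptance_rate]),
        meta={
            "seed": int(seed),
            "proposal": proposal_name,
            "temperatures": temps,
            "swap_interval": int(swap_interval),
            "thinning": int(thinning),
            "polytope_label": problem.polytope.label,
            "burn_in_draws": 0,
        },
    )
    stats = SwapStatistics(attempts=attempts[:max(K - 1, 0)] if K > 1 else attempts[:0],
                           accepts=accepts[:max(K - 1, 0)] if K > 1 else accepts[:0])
    return batch, stats


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def checkpoint(chain: "MarkovChain | ChainState") -> bytes:
    """Serialize a chain (or its state) to a checksummed, schema-tagged blob."""
    state = chain.state() if isinstance(chain, MarkovChain) else chain
    payload = pickle.dumps({"schema": _CHECKPOINT_SCHEMA, "state": state})
    digest = hashlib.sha256(payload).digest()
    return _CHECKPOINT_MAGIC + digest + payload


def restore(blob: bytes, problem: Problem) -> MarkovChain:
    """Rebuild a chain from :func:`checkpoint` output.

    Verifies the checksum and schema tag, then revalidates the cached
    log-density against a fresh model evaluation; the resumed chain continues
    the draw stream bit-for-bit.
    """
    if not blob.startswith(_CHECKPOINT_MAGIC):
        raise CheckpointError("not a chordwalk checkpoint (bad magic header)")
    head = len(_CHECKPOINT_MAGIC)
    digest, payload = blob[head:head + 32], blob[head + 32:]
    if hashlib.sha256(payload).digest() != digest:
        raise CheckpointError("checkpoint blob is corrupted (checksum mismatch)")
    doc = pickle.loads(payload)
    if doc.get("schema") != _CHECKPOINT_SCHEMA:
        raise CheckpointError(
            f"incompatible checkpoint schema {doc.get('schema')!r}"
        )
    return MarkovChain.from_state(problem, doc["state"])
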