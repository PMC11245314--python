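"""Sampling engine: RNG streams, Metropolis filter, multi-chain driver,
tuning, tempering, checkpointing."""

import numpy as np
import pytest
from scipy import integrate, stats

import chordwalk as cw
from chordwalk.engine import _default_start
from chordwalk.exceptions import (
    CheckpointError,
    FeasibilityError,
    InfeasibleError,
    NotTunableError,
    PluginError,
    RegistryError,
)
from chordwalk.models import Problem
from chordwalk.proposals import Proposal


# ---------------------------------------------------------------------------
# RNG
# ---------------------------------------------------------------------------

def test_make_rng_reproducible():
    a = cw.make_rng(42, 3).uniform(size=100)
    b = cw.make_rng(42, 3).uniform(size=100)
    assert np.array_equal(a, b)


def test_make_rng_streams_independent():
    u0 = cw.make_rng(42, 0).uniform(size=10 ** 4)
    u1 = cw.make_rng(42, 1).uniform(size=10 ** 4)
    assert not np.array_equal(u0, u1)
    _, p = stats.ks_2samp(u0, u1)
    assert p > 0.001


def test_make_rng_uniform_mean_law_of_large_numbers():
    u = cw.make_rng(7, 0).uniform(size=10 ** 6)
    assert abs(u.mean() - 0.5) < 3 * (1 / np.sqrt(12)) / 10 ** 3


# ---------------------------------------------------------------------------
# Metropolis step
# ---------------------------------------------------------------------------

def test_uniform_target_always_accepts(uniform_square_problem):
    chain = cw.MarkovChain(uniform_square_problem, "hit_and_run_uniform", seed=0)
    for _ in range(200):
        assert chain.step()


class _OutsideProposal(Proposal):
    """Kernel stub that always proposes an infeasible point."""

    def propose(self, rng):
        return np.full(self.problem.dim, 99.0)


def test_infeasible_candidate_rejected_without_model_evaluation(unit_square):
    calls = []

    def spy_logdensity(x):
        calls.append(x)
        return 0.0

    problem = Problem(unit_square, cw.Model(log_density=spy_logdensity))
    chain = cw.MarkovChain(problem, "hit_and_run_uniform", seed=0,
                           start=np.array([0.5, 0.5]))
    calls.clear()  # drop the initial-state evaluation
    chain.proposal = _OutsideProposal(problem, np.array([0.5, 0.5]))
    assert not chain.step()
    assert np.array_equal(chain.position, [0.5, 0.5])
    assert calls == []


def test_nan_model_raises_plugin_error(unit_square):
    problem = Problem(unit_square, cw.Model(log_density=lambda x: 0.0))
    chain = cw.MarkovChain(problem, "hit_and_run_uniform", seed=0)
    object.__setattr__(problem.model, "log_density", lambda x: float("nan"))
    with pytest.raises(PluginError):
        chain.step()


def test_functional_metropolis_step_counts(uniform_square_problem):
    chain = cw.MarkovChain(uniform_square_problem, "hit_and_run_uniform", seed=0)
    state = chain.state()
    new = cw.metropolis_step(state, chain.proposal, uniform_square_problem, chain.rng)
    assert new.step_count == state.step_count + 1
    assert new.accept_count == state.accept_count + 1  # uniform target accepts


def test_truncated_gaussian_mean_quadrature_oracle(unit_interval):
    """1-D N(0.5, 0.1^2) restricted to [0,1]: the chain mean matches the
    truncated-normal mean computed by numerical integration."""
    target = cw.gaussian_model([0.5], [[0.01]])
    problem = Problem(unit_interval, target)
    batch = cw.sample(problem, "gaussian_hit_and_run", n_chains=1,
                      n_samples=5 * 10 ** 4, seed=6,
                      proposal_params={"step_size": 0.1})
    x = batch.draws[0, :, 0]

    dens = lambda t: np.exp(target.log_density(np.array([t])))
    Z, _ = integrate.quad(dens, 0, 1)
    mean, _ = integrate.quad(lambda t: t * dens(t) / Z, 0, 1)

    ess = cw.effective_sample_size(x[None, :, None])[0]
    se = x.std(ddof=1) / np.sqrt(ess)
    assert abs(x.mean() - mean) < 3 * se


# ---------------------------------------------------------------------------
# multi-chain driver
# ---------------------------------------------------------------------------

def test_sample_shape_bookkeeping(uniform_square_problem):
    batch = cw.sample(uniform_square_problem, "hit_and_run_uniform",
                      n_chains=4, n_samples=100, thinning=2, seed=0)
    assert batch.draws.shape == (4, 100, 2)
    chain = cw.MarkovChain(uniform_square_problem, "hit_and_run_uniform", seed=0)
    chain.run(100, thinning=2)
    assert chain.step_count == 200


def test_sample_same_seed_bit_identical(uniform_square_problem):
    a = cw.sample(uniform_square_problem, "hit_and_run_uniform",
                  n_chains=3, n_samples=200, seed=5)
    b = cw.sample(uniform_square_problem, "hit_and_run_uniform",
                  n_chains=3, n_samples=200, seed=5)
    assert np.array_equal(a.draws, b.draws)


def test_sample_infeasible_polytope_fails_before_stepping():
    P = cw.Polytope([[1.0], [-1.0]], [0.0, -1.0])
    with pytest.raises(InfeasibleError):
        cw.sample(Problem(P, cw.uniform_model()), "hit_and_run_uniform",
                  n_chains=1, n_samples=10, seed=0)


def test_sample_unknown_proposal_name(uniform_square_problem):
    with pytest.raises(RegistryError, match="coordinate_hit_and_run"):
        cw.sample(uniform_square_problem, "nope", n_chains=1, n_samples=10, seed=0)


def test_default_starts_are_jittered_and_interior(uniform_square_problem):
    starts = {tuple(_default_start(uniform_square_problem, cw.make_rng(0, c)))
              for c in range(4)}
    assert len(starts) == 4  # all distinct
    for s in starts:
        assert cw.contains(uniform_square_problem.polytope, np.array(s))
        assert np.linalg.norm(np.array(s) - 0.5) <= 0.05 + 1e-12


def test_chrrt_converges_on_hypercube16():
    """CHRRT preset (rounding + coordinate hit-and-run + thinning) reaches
    split R-hat <= 1.01 on every coordinate of a 16-D hypercube."""
    P = cw.hypercube(16)
    rounded, record = cw.round_polytope(P)
    problem = Problem(rounded, cw.uniform_model(), record)
    batch = cw.sample(problem, "coordinate_hit_and_run", n_chains=4,
                      n_samples=1000, thinning=10, seed=12)
    rhat = cw.split_rhat(batch.draws)
    assert np.all(rhat <= 1.01)


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def test_tuning_reaches_target_rate(unit_square):
    # sd 0.05: the target must be peaked enough that the acceptance-rate
    # curve actually crosses the 0.5 target as the step size grows
    target = cw.gaussian_model([0.5, 0.5], 0.05 ** 2 * np.eye(2))
    problem = Problem(unit_square, target)
    result = cw.tune_acceptance_rate(problem, "gaussian_hit_and_run",
                                     target_rate=0.5, n_tuning=5000, seed=1)
    assert abs(result.achieved_rate - 0.5) < 0.1
    assert result.step_size > 0


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.2])
def test_tuning_target_rate_must_be_open_interval(uniform_square_problem, bad):
    with pytest.raises(ValueError):
        cw.tune_acceptance_rate(uniform_square_problem, "gaussian_hit_and_run",
                                target_rate=bad, n_tuning=100, seed=0)


def test_tuning_requires_step_size(uniform_square_problem):
    with pytest.raises(NotTunableError):
        cw.tune_acceptance_rate(uniform_square_problem, "hit_and_run_uniform",
                                target_rate=0.5, n_tuning=100, seed=0)


# ---------------------------------------------------------------------------
# parallel tempering
# ---------------------------------------------------------------------------

def _bimodal_problem():
    mix = cw.mixture_model(
        [cw.gaussian_model([0.2, 0.2], 0.03 ** 2 * np.eye(2)),
         cw.gaussian_model([0.8, 0.8], 0.03 ** 2 * np.eye(2))],
        [0.5, 0.5],
    )
    return Problem(cw.hypercube(2), mix)


def test_pt_degenerate_equal_temperatures_swap_always():
    problem = _bimodal_problem()
    _, stats_ = cw.parallel_tempering(problem, "gaussian_hit_and_run",
                                      [1.0, 1.0], n_samples=200,
                                      swap_interval=5, seed=0,
                                      proposal_params={"step_size": 0.1})
    assert np.all(stats_.rates == 1.0)


def test_pt_single_temperature_equals_plain_sampling(uniform_square_problem):
    pt_batch, stats_ = cw.parallel_tempering(
        uniform_square_problem, "hit_and_run_uniform", [1.0],
        n_samples=300, swap_interval=5, seed=9)
    plain = cw.sample(uniform_square_problem, "hit_and_run_uniform",
                      n_chains=1, n_samples=300, seed=9)
    assert np.array_equal(pt_batch.draws, plain.draws)
    assert stats_.attempts.size == 0


@pytest.mark.parametrize("ladder", [[2.0, 4.0], [1.0, 4.0, 2.0]])
def test_pt_ladder_validation(uniform_square_problem, ladder):
    with pytest.raises(ValueError):
        cw.parallel_tempering(uniform_square_problem, "hit_and_run_uniform",
                              ladder, n_samples=10, seed=0)


def test_pt_mixes_across_separated_modes():
    """The bimodal 2-D target: PT visits both modes in balanced proportion
    while a matched-budget single chain stays stuck in one."""
    problem = _bimodal_problem()
    pt_batch, _ = cw.parallel_tempering(
        problem, "gaussian_hit_and_run", [1.0, 4.0, 16.0, 64.0],
        n_samples=10 ** 4, swap_interval=10, seed=1,
        proposal_params={"step_size": 0.12})
    occ_pt = float(np.mean(pt_batch.draws[0, :, 0] < 0.5))
    single = cw.sample(problem, "gaussian_hit_and_run", n_chains=1,
                       n_samples=4 * 10 ** 4, seed=1,
                       proposal_params={"step_size": 0.12})
    occ_single = float(np.mean(single.draws[0, :, 0] < 0.5))
    assert 0.35 < occ_pt < 0.65
    assert not (0.35 < occ_single < 0.65)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def test_checkpoint_resume_equals_uninterrupted(unit_square):
    target = cw.gaussian_model([0.5, 0.5], 0.05 * np.eye(2))
    problem = Problem(unit_square, target)
    full = cw.MarkovChain(problem, "gaussian_hit_and_run", seed=3,
                          proposal_params={"step_size": 0.2})
    uninterrupted = full.run(1000)

    part = cw.MarkovChain(problem, "gaussian_hit_and_run", seed=3,
                          proposal_params={"step_size": 0.2})
    first = part.run(500)
    blob = cw.checkpoint(part)
    resumed = cw.restore(blob, problem)
    second = resumed.run(500)
    assert np.array_equal(np.vstack([first, second]), uninterrupted)


def test_checkpoint_restores_adaptive_internals(uniform_square_problem):
    full = cw.MarkovChain(uniform_square_problem, "adaptive_svd", seed=4)
    uninterrupted = full.run(400)
    part = cw.MarkovChain(uniform_square_problem, "adaptive_svd", seed=4)
    first = part.run(150)
    resumed = cw.restore(cw.checkpoint(part), uniform_square_problem)
    second = resumed.run(250)
    assert np.array_equal(np.vstack([first, second]), uninterrupted)


def test_checkpoint_corruption_detected(uniform_square_problem):
    chain = cw.MarkovChain(uniform_square_problem, "hit_and_run_uniform", seed=0)
    blob = bytearray(cw.checkpoint(chain))
    blob[-1] ^= 0xFF
    with pytest.raises(CheckpointError, match="checksum"):
        cw.restore(bytes(blob), uniform_square_problem)
    with pytest.raises(CheckpointError, match="magic"):
        cw.restore(b"garbage", uniform_square_problem)


def test_restore_validates_cached_log_density(unit_square):
    problem = Problem(unit_square, cw.gaussian_model([0.5, 0.5], np.eye(2)))
    chain = cw.MarkovChain(problem, "hit_and_run_uniform", seed=0)
    state = chain.state()
    state.log_density_cached += 1.0  # simulate stale cache
    with pytest.raises(CheckpointError, match="log-density"):
        cw.MarkovChain.from_state(problem, state)


# ---------------------------------------------------------------------------
# support conservation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", ["hit_and_run_uniform", "gaussian_hit_and_run",
                                  "coordinate_hit_and_run", "adaptive_svd"])
def test_no_stored_draw_ever_leaves_the_polytope(name):
    target = cw.gaussian_model(np.full(3, 0.3), 0.02 * np.eye(3))
    for P in (cw.hypercube(3), cw.simplex(3)):
        problem = Problem(P, target)
        params = {"step_size": 0.15} if name == "gaussian_hit_and_run" else None
        batch = cw.sample(problem, name, n_chains=2, n_samples=1000, seed=17,
                          proposal_params=params)
        flat = batch.draws.reshape(-1, 3)
        assert np.all(flat @ P.A.T <= P.b[None, :] + 1e-9)
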