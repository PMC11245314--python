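"""Convergence and efficiency diagnostics.

Computed natively: classic split Gelman–Rubin R-hat (half-chains, not
rank-normalized) and autocorrelation-based effective sample size with Geyer's
initial-positive-sequence truncation.  Visualization is deliberately out of
scope — draws are laid out as (chain, draw, dim) arrays so standard MCMC
analysis tooling consumes them directly.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .engine import SampleBatch


def _as_cid(draws: np.ndarray) -> np.ndarray:
    """Coerce to (chains, iterations, dims)."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws[None, :, None]
    elif draws.ndim == 2:  # (iterations, dims) single chain
        draws = draws[None, :, :]
    if draws.ndim != 3:
        raise ValueError("draws must have shape (chains, iterations, dims)")
    return draws


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Classic split-R-hat per dimension.

    Each chain is halved; with W the mean within-half-chain variance and B
    the between-half-chain variance of means (times N),
    ``rhat = sqrt(((N-1)/N * W + B/N) / W)``.  Chains with zero within
    variance (all-constant) yield NaN — an undefined-diagnostic signal, not a
    crash.
    """
    draws = _as_cid(draws)
    C, N, D = draws.shape
    if C < 2:
        raise ValueError("split_rhat needs at least 2 chains")
    if N < 4:
        raise ValueError("split_rhat needs at least 4 iterations")
    half = N // 2
    halves = np.concatenate([draws[:, :half, :], draws[:, half:2 * half, :]], axis=0)
    means = halves.mean(axis=1)                     # (2C, D)
    variances = halves.var(axis=1, ddof=1)          # (2C, D)
    W = variances.mean(axis=0)
    B = half * means.var(axis=0, ddof=1)
    out = np.full(D, np.nan)
    ok = W > 0
    if not np.all(ok):
        warnings.warn("split_rhat undefined for constant chains (W = 0)",
                      RuntimeWarning, stacklevel=2)
    var_plus = (half - 1) / half * W[ok] + B[ok] / half
    out[ok] = np.sqrt(var_plus / W[ok])
    return out


def _autocorrelations(x: np.ndarray) -> np.ndarray:
    """Biased-normalization autocorrelation of a 1-d series via FFT."""
    n = x.size
    x = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n] / n
    if acov[0] <= 0:
        return np.zeros(n)
    return acov / acov[0]


def effective_sample_size(
    draws: np.ndarray, return_flags: bool = False
) -> "np.ndarray | tuple[np.ndarray, np.ndarray]":
    """Autocorrelation-based ESS per dimension, combined across chains.

    Autocorrelations are computed per chain on centered draws and averaged;
    Geyer's initial positive sequence then truncates: adjacent-pair sums
    ``Gamma_m = rho_{2m} + rho_{2m+1}`` are accumulated while positive, and
    ``ESS = C*N / (-1 + 2 * sum Gamma_m)``, capped at the total draw count
    C*N.  Constant dimensions get ESS 1 and a degeneracy flag.
    """
    draws = _as_cid(draws)
    C, N, D = draws.shape
    if N < 10:
        raise ValueError("effective_sample_size needs at least 10 iterations")
    ess = np.empty(D)
    flags = np.zeros(D, dtype=bool)
    for d in range(D):
        if np.all(draws[:, :, d].std(axis=1) == 0.0):
            ess[d] = 1.0
            flags[d] = True
            continue
        rho = np.mean([_autocorrelations(draws[c, :, d]) for c in range(C)], axis=0)
        tau = -1.0
        m = 0
        while 2 * m + 1 < N:
            gamma = rho[2 * m] + rho[2 * m + 1]
            if gamma <= 0.0:
                break
            tau += 2.0 * gamma
            m += 1
        tau = max(tau, 1.0 / (C * N))
        ess[d] = min(C * N / tau, C * N)
    if np.any(flags):
        warnings.warn("constant chain: ESS reported as 1", RuntimeWarning,
                      stacklevel=2)
    return (ess, flags) if return_flags else ess


def summarize(batch: "SampleBatch | np.ndarray",
              acceptance_rates: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-dimension summary table.

    Columns: mean, sd, q2.5, median, q97.5, rhat, ess, acceptance_rate.
    Quantiles use linear interpolation; R-hat is NaN for single-chain input.
    """
    if isinstance(batch, SampleBatch):
        draws = batch.draws
        if acceptance_rates is None:
            acceptance_rates = batch.acceptance_rates
    else:
        draws = _as_cid(batch)
    C, N, D = draws.shape
    flat = draws.reshape(C * N, D)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if C >= 2 and N >= 4:
            rhat = split_rhat(draws)
        else:
            rhat = np.full(D, np.nan)
        ess = effective_sample_size(draws) if N >= 10 else np.full(D, np.nan)
    q = np.percentile(flat, [2.5, 50.0, 97.5], axis=0, method="linear")
    rate = float(np.mean(acceptance_rates)) if acceptance_rates is not None else np.nan
    return pd.DataFrame({
        "mean": flat.mean(axis=0),
        "sd": flat.std(axis=0, ddof=1) if C * N > 1 else np.zeros(D),
        "q2.5": q[0],
        "median": q[1],
        "q97.5": q[2],
        "rhat": rhat,
        "ess": ess,
        "acceptance_rate": rate,
    }, index=[f"dim_{d}" for d in range(D)])
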