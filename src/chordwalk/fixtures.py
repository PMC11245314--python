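"""Synthetic fixture generator.

Writes self-contained sampling problems to disk — polytope CSVs, an optional
model block, a run config, and a manifest recording the fixture's ANALYTIC
ground truth where known (coordinate means/variances under the uniform law,
dimension, Chebyshev data).  Every manifest claim is confirmed by the
corresponding library computation at generation time, so a fixture that
disagrees with the library can never be produced silently.

These synthetic problems stand in for the large domain models (metabolic
networks) that real deployments sample; they exercise the same code paths at
desk scale.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .polytope import (
    Polytope,
    birkhoff,
    chebyshev_center,
    contains,
    hypercube,
    simplex,
)
from . import io as cwio

FIXTURE_KINDS = (
    "hypercube", "simplex", "birkhoff", "stretched_box",
    "random_hpoly", "bimodal_gaussian",
)

#: anisotropy of the stretched box: last axis is this many times longer
STRETCH_FACTOR = 100.0

#: bimodal fixture geometry: two Gaussians on the unit square
BIMODAL_MEANS = ((0.2, 0.2), (0.8, 0.8))
BIMODAL_SD = 0.03


def make_fixture(kind: str, n: int, seed: int = 0, out_dir=".", params=None) -> dict:
    """Write fixture files for ``kind`` and return the manifest dict.

    Files written: ``A.csv``/``b.csv`` (+ ``S.csv``/``c.csv`` or transform
    CSVs where applicable), ``config.json`` bundling everything, and
    ``manifest.json`` with the analytic ground truth.
    """
    params = dict(params or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    builder = _BUILDERS.get(kind)
    if builder is None:
        raise ValueError(f"unknown fixture kind {kind!r}; valid: {FIXTURE_KINDS}")
    P, config_extra, truth = builder(n, seed, params)

    config = {"polytope": cwio.write_polytope(P, out)}
    record = config_extra.pop("_transform_record", None)
    if record is not None:
        config["transform"] = cwio.write_transform(record, out)
    config.update(config_extra)
    config.setdefault("model", {"name": "uniform"})
    config.setdefault("sampler", {"proposal": "hit_and_run_uniform", "seed": seed})
    (out / "config.json").write_text(json.dumps(config, indent=2, sort_keys=True))

    cheb = chebyshev_center(P)
    manifest = {
        "kind": kind,
        "n": n,
        "seed": seed,
        "dimension": P.dim,
        "chebyshev_center": [float(x) for x in cheb.center],
        "chebyshev_radius": float(cheb.radius),
    }
    manifest.update(truth)
    _confirm(manifest, P, cheb)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _confirm(manifest: dict, P: Polytope, cheb) -> None:
    """Generation-time self-check of manifest ground truth."""
    assert manifest["dimension"] == P.dim
    if "expected_chebyshev_radius" in manifest:
        if abs(cheb.radius - manifest["expected_chebyshev_radius"]) > 1e-8:
            raise AssertionError(
                "fixture ground truth disagrees with library Chebyshev radius"
            )
    if not contains(P, cheb.center, tol=1e-9):
        raise AssertionError("Chebyshev center fails membership")


# -- builders ----------------------------------------------------------------

def _hypercube(n, seed, params):
    P = hypercube(n)
    truth = {
        "uniform_mean": [0.5] * n,
        "uniform_variance": [1.0 / 12.0] * n,
        "expected_chebyshev_radius": 0.5,
    }
    return P, {}, truth


def _simplex(n, seed, params):
    P = simplex(n)
    mean = 1.0 / (n + 1)
    var = n / ((n + 1.0) ** 2 * (n + 2.0))  # Beta(1, n) moments
    truth = {"uniform_mean": [mean] * n, "uniform_variance": [var] * n}
    return P, {}, truth


def _birkhoff(n, seed, params):
    if n < 2:
        raise ValueError("birkhoff fixture requires n >= 2")
    reduced, record = birkhoff(n)
    truth = {
        "reduced_dimension": (n - 1) ** 2,
        "full_dimension": n * n,
        "uniform_mean_full": [1.0 / n] * (n * n),
    }
    if reduced.dim != (n - 1) ** 2:
        raise AssertionError("Birkhoff reduced dimension mismatch")
    return reduced, {"_transform_record": record}, truth


def _stretched_box(n, seed, params):
    """Elongated box, rotated so its principal axes do NOT align with the
    coordinate axes.

    The rotation is what makes the fixture hard: on an axis-aligned box a
    coordinate hit-and-run move redraws the full chord of the chosen axis, so
    anisotropy costs nothing; once rotated, every coordinate chord is clipped
    by the thin directions and unrounded coordinate walks crawl.  Set
    ``params={'angle': 0}`` for the axis-aligned variant.
    """
    if n < 2:
        raise ValueError("stretched_box fixture requires n >= 2")
    stretch = float(params.get("stretch", STRETCH_FACTOR))
    angle = float(params.get("angle", np.pi / 6.0))
    eye = np.eye(n)
    hi = np.ones(n)
    hi[-1] = stretch
    # rotate in the (0, n-1) plane and recenter the box at the origin
    R = np.eye(n)
    c, s = np.cos(angle), np.sin(angle)
    R[0, 0] = R[n - 1, n - 1] = c
    R[0, n - 1], R[n - 1, 0] = -s, s
    A = np.vstack([eye, -eye]) @ R.T
    b = np.concatenate([hi / 2.0, hi / 2.0])
    P = Polytope(A, b, label=f"stretched_box({n},{stretch:g})")
    var_axis = np.full(n, 1.0 / 12.0)
    var_axis[-1] = stretch ** 2 / 12.0
    cov = R @ np.diag(var_axis) @ R.T
    truth = {
        "uniform_mean": [0.0] * n,
        "uniform_variance": [float(v) for v in np.diag(cov)],
        "stretch": stretch,
        "rotation_angle": angle,
        "long_axis_direction": [float(v) for v in R[:, n - 1]],
    }
    return P, {}, truth


def _random_hpoly(n, seed, params):
    """Box [-1,1]^n cut by k random half-spaces through interior points.

    Each cut's normal is oriented so the origin stays strictly feasible,
    guaranteeing nonemptiness; the box guarantees boundedness.
    """
    k = int(params.get("k", 2 * n))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    eye = np.eye(n)
    rows, offs = [eye, -eye], [np.ones(n), np.ones(n)]
    cut_A, cut_b = [], []
    while len(cut_A) < k:
        u = rng.standard_normal(n)
        u /= np.linalg.norm(u)
        p = rng.uniform(-0.5, 0.5, size=n)  # interior point of the box
        if abs(u @ p) < 1e-3:
            continue
        if u @ p < 0:
            u = -u
        cut_A.append(u)
        cut_b.append(u @ p)
    A = np.vstack(rows + [np.array(cut_A)])
    b = np.concatenate(offs + [np.array(cut_b)])
    P = Polytope(A, b, label=f"random_hpoly({n},seed={seed})")
    return P, {}, {"n_cuts": k, "origin_feasible": True}


def _bimodal_gaussian(n, seed, params):
    if n != 2:
        raise ValueError("bimodal_gaussian fixture is 2-dimensional (n=2)")
    sd = float(params.get("sd", BIMODAL_SD))
    P = hypercube(2)
    model_block = {
        "name": "mixture",
        "weights": [0.5, 0.5],
        "components": [
            {"name": "gaussian", "mean": list(m),
             "covariance": [[sd ** 2, 0.0], [0.0, sd ** 2]]}
            for m in BIMODAL_MEANS
        ],
    }
    truth = {
        "mode_centers": [list(m) for m in BIMODAL_MEANS],
        "mode_sd": sd,
        "expected_mode_occupancy": 0.5,
        "expected_chebyshev_radius": 0.5,
    }
    return P, {"model": model_block}, truth


_BUILDERS = {
    "hypercube": _hypercube,
    "simplex": _simplex,
    "birkhoff": _birkhoff,
    "stretched_box": _stretched_box,
    "random_hpoly": _random_hpoly,
    "bimodal_gaussian": _bimodal_gaussian,
}
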