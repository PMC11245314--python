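"""File formats.

Matrices and vectors travel as header-free, comma-delimited text, row-major,
0-based everywhere.  Runs are described by one structured config document
(JSON or YAML, auto-detected) with blocks ``polytope``, ``equalities``
(optional), ``model`` (optional, default uniform), ``sampler`` and ``output``;
file paths inside a config are resolved relative to the config's directory.

Sample batches are written either as one CSV per chain plus a JSON metadata
sidecar, or as a packed columnar binary: a single JSON header line (shape,
dtype, layout) followed by raw little-endian float64 bytes in Fortran
(column-major) order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .engine import SampleBatch
from .exceptions import ConfigError
from .models import Model, Problem, gaussian_model, mixture_model, uniform_model
from .polytope import EqualitySystem, Polytope, TransformRecord, embed_equalities


# ---------------------------------------------------------------------------
# delimited-text matrices
# ---------------------------------------------------------------------------

def save_matrix(path, M) -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(M, dtype=float)), delimiter=",")


def load_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def save_vector(path, v) -> None:
    np.savetxt(path, np.asarray(v, dtype=float).reshape(-1), delimiter=",")


def load_vector(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",").reshape(-1)


# ---------------------------------------------------------------------------
# config documents
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Parse a JSON or YAML config; the format is chosen by content."""
    path = Path(path)
    text = path.read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError:
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: neither valid JSON nor YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return doc


def _resolve(base: Path, p) -> Path:
    p = Path(p)
    return p if p.is_absolute() else base / p


def polytope_from_config(config: dict, base_dir) -> Polytope:
    base = Path(base_dir)
    try:
        block = config["polytope"]
        A = load_matrix(_resolve(base, block["A"]))
        b = load_vector(_resolve(base, block["b"]))
    except KeyError as exc:
        raise ConfigError(f"config missing polytope entry: {exc}") from exc
    return Polytope(A, b, label=block.get("label"))


def equalities_from_config(config: dict, base_dir) -> Optional[EqualitySystem]:
    block = config.get("equalities")
    if block is None:
        return None
    base = Path(base_dir)
    try:
        S = load_matrix(_resolve(base, block["S"]))
        c = load_vector(_resolve(base, block["c"]))
    except KeyError as exc:
        raise ConfigError(f"config missing equalities entry: {exc}") from exc
    return EqualitySystem(S, c)


def model_from_config(config: dict) -> Model:
    """Build a built-in model from a config block (plugins are API-only)."""
    block = config.get("model") or {"name": "uniform"}
    name = block.get("name", "uniform")
    if name == "uniform":
        return uniform_model()
    if name == "gaussian":
        try:
            return gaussian_model(block["mean"], block["covariance"])
        except KeyError as exc:
            raise ConfigError(f"gaussian model block missing {exc}") from exc
    if name == "mixture":
        comps = block.get("components")
        weights = block.get("weights")
        if not comps or weights is None:
            raise ConfigError("mixture model block needs 'components' and 'weights'")
        return mixture_model([model_from_config({"model": c}) for c in comps], weights)
    raise ConfigError(f"unknown model name {name!r} (uniform, gaussian, mixture)")


def problem_from_config(config: dict, base_dir) -> Problem:
    """Assemble a Problem, embedding an equality system when present."""
    P = polytope_from_config(config, base_dir)
    eq = equalities_from_config(config, base_dir)
    model = model_from_config(config)
    transform = None
    if eq is not None:
        P, transform = embed_equalities(eq, P)
    return Problem(polytope=P, model=model, transform=transform)


# ---------------------------------------------------------------------------
# polytope / transform writers
# ---------------------------------------------------------------------------

def write_polytope(P: Polytope, out_dir, prefix: str = "") -> dict:
    """Write A/b as CSVs; returns the polytope config block (relative paths)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a_name, b_name = f"{prefix}A.csv", f"{prefix}b.csv"
    save_matrix(out / a_name, P.A)
    save_vector(out / b_name, P.b)
    block = {"A": a_name, "b": b_name}
    if P.label:
        block["label"] = P.label
    return block


def write_equalities(eq: EqualitySystem, out_dir, prefix: str = "") -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s_name, c_name = f"{prefix}S.csv", f"{prefix}c.csv"
    save_matrix(out / s_name, eq.S)
    save_vector(out / c_name, eq.c)
    return {"S": s_name, "c": c_name}


def write_transform(record: TransformRecord, out_dir, prefix: str = "") -> dict:
    """Serialize a transform next to its samples so original coordinates are
    always recoverable."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    basis_name, shift_name = f"{prefix}basis.csv", f"{prefix}shift.csv"
    save_matrix(out / basis_name, record.basis)
    save_vector(out / shift_name, record.shift)
    return {"basis": basis_name, "shift": shift_name}


def read_transform(block: dict, base_dir) -> TransformRecord:
    base = Path(base_dir)
    return TransformRecord(
        basis=load_matrix(_resolve(base, block["basis"])),
        shift=load_vector(_resolve(base, block["shift"])),
    )


# ---------------------------------------------------------------------------
# sample batch writers
# ---------------------------------------------------------------------------

def write_batch(batch: SampleBatch, out_dir, fmt: str = "csv") -> None:
    """Write draws plus a JSON metadata sidecar (``meta.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = dict(batch.meta)
    meta["shape"] = list(batch.draws.shape)
    meta["acceptance_rates"] = [float(r) for r in batch.acceptance_rates]
    meta["format"] = fmt
    if fmt == "csv":
        for c in range(batch.n_chains):
            save_matrix(out / f"chain_{c}.csv", batch.draws[c])
    elif fmt == "binary":
        header = json.dumps({
            "dtype": "<f8", "order": "F", "shape": list(batch.draws.shape),
        }).encode() + b"\n"
        with open(out / "samples.cwb", "wb") as fh:
            fh.write(header)
            fh.write(np.asfortranarray(batch.draws).tobytes(order="F"))
    else:
        raise ValueError(f"unknown batch format {fmt!r}")
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_batch(in_dir) -> SampleBatch:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    shape = tuple(meta["shape"])
    if meta.get("format") == "binary":
        with open(src / "samples.cwb", "rb") as fh:
            json.loads(fh.readline())
            draws = np.frombuffer(fh.read(), dtype="<f8").reshape(shape, order="F")
        draws = np.ascontiguousarray(draws)
    else:
        draws = np.stack([
            load_matrix(src / f"chain_{c}.csv") for c in range(shape[0])
        ])
        draws = draws.reshape(shape)
    return SampleBatch(
        draws=draws,
        acceptance_rates=np.asarray(meta.get("acceptance_rates", []), dtype=float),
        meta={k: v for k, v in meta.items()
              if k not in ("shape", "acceptance_rates", "format")},
    )
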