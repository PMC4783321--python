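"""Result serialization and deterministic test fixtures.

Snapshots go to delimited text with explicit coordinate columns (x[,y],u)
and, optionally, to a self-describing .npz array container; per-step
diagnostics go to CSV and run metadata (config echo, grid/boundary
conventions, content hash) to JSON.  Text output uses 17 significant
digits, so re-reading reproduces the arrays bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .etd import SimulationResult

__all__ = ["write_result", "read_result", "make_fixture"]

_FMT = "%.17e"


def _content_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_result(
    result: SimulationResult,
    config: dict,
    outdir,
    grid=None,
    formats: tuple[str, ...] = ("txt",),
) -> list[Path]:
    """Write snapshots, diagnostics and metadata under ``outdir``.

    A ``.incomplete`` marker exists while writing and is removed on
    success, so interrupted runs are detectable.  Returns the files
    written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".incomplete"
    marker.touch()
    written: list[Path] = []

    coords = None
    if grid is not None:
        coords = grid.meshgrid(interior=True)

    if "txt" in formats:
        for i, (t, u) in enumerate(zip(result.times, result.snapshots)):
            p = out / f"snapshot_{i:04d}.txt"
            header = f"kiss-sim snapshot\nt = {float(t):.17e}\ncolumns: "
            if coords is None:
                header += "u"
                data = np.asarray(u).reshape(-1, 1)
            elif len(coords) == 1:
                header += "x u"
                data = np.column_stack([coords[0], u])
            else:
                header += "x y u"
                X, Y = coords
                data = np.column_stack([X.ravel(), Y.ravel(), np.asarray(u).ravel()])
            np.savetxt(p, data, fmt=_FMT, header=header)
            written.append(p)
    if "npz" in formats:
        p = out / "snapshots.npz"
        arrays = {"times": result.times}
        for i, u in enumerate(result.snapshots):
            arrays[f"u_{i:04d}"] = np.asarray(u)
        if coords is not None:
            for j, c in enumerate(coords):
                arrays[f"coord_{j}"] = np.asarray(c)
        np.savez(p, **arrays)
        written.append(p)

    p = out / "diagnostics.csv"
    result.diagnostics.to_csv(p, index=False, float_format="%.17e")
    written.append(p)

    meta = {
        "config": config,
        "result": {
            "blowup": result.blowup,
            "t_blowup": result.t_blowup,
            "snapshot_times": [float(t) for t in result.times],
            **{k: v for k, v in result.meta.items()},
        },
        "conventions": {
            "grid_rule": "h=(hi-lo)/(N-1), endpoints included (dirichlet0); "
                         "h=(hi-lo)/N, right endpoint omitted (periodic)",
            "dirichlet_closure": "odd-reflection ghosts, endpoints held at 0",
            "c_stage": "a_n-form (Cox-Matthews)",
            "mass_rule": "sum(u)*h per axis on the unknown nodes",
        },
        "content_hash": _content_hash(config),
    }
    p = out / "metadata.json"
    p.write_text(json.dumps(meta, indent=2, default=str))
    written.append(p)

    marker.unlink()
    return written


def read_result(outdir) -> dict:
    """Re-read a written run: snapshots, diagnostics and metadata."""
    out = Path(outdir)
    if (out / ".incomplete").exists():
        raise IOError(f"{outdir}: run output is marked incomplete")
    meta = json.loads((out / "metadata.json").read_text())
    snaps = []
    times = []
    for p in sorted(out.glob("snapshot_*.txt")):
        with open(p) as fh:
            fh.readline()
            t_line = fh.readline()
        times.append(float(t_line.split("=")[1]))
        data = np.loadtxt(p)
        snaps.append(data[:, -1])
    diag = pd.read_csv(out / "diagnostics.csv")
    return {
        "times": np.asarray(times),
        "snapshots": snaps,
        "diagnostics": diag,
        "metadata": meta,
    }


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------


def make_fixture(kind: str, size: int | None = None):
    """Small deterministic instances for testing; no randomness anywhere.

    Kinds: ``grid1d_small`` (N=21 on [-1,1]), ``grid2d_small`` (21x21 on
    [-10,10]), ``scalar_ode`` (u' = u^2, u0 = 1, exact u(t) = 1/(1-t)),
    ``table1_problem`` (the 1-D nonlinear benchmark at a reduced N).
    """
    from .discretize import (DiagonalOperator, GridSpec, SemilinearSystem,
                             build_grid)

    if kind == "grid1d_small":
        return build_grid(GridSpec(dim=1, lo=-1.0, hi=1.0, N=size or 21))
    if kind == "grid2d_small":
        return build_grid(GridSpec(dim=2, lo=-10.0, hi=10.0, N=size or 21))
    if kind == "scalar_ode":
        system = SemilinearSystem(
            L=DiagonalOperator(np.zeros(1)),
            F=lambda u, t: u**2,
        )
        return {
            "system": system,
            "u0": np.ones(1),
            "exact": lambda t: 1.0 / (1.0 - t),
            "description": "u' = u^2, u0 = 1, blow-up at t = 1",
        }
    if kind == "table1_problem":
        from .experiments import test1_problem

        return test1_problem(N=size or 50)
    raise ValueError(
        f"unknown fixture kind {kind!r}; choose from grid1d_small, "
        f"grid2d_small, scalar_ode, table1_problem"
    )
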