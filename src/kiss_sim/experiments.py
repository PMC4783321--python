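"""Quantitative studies: accuracy tables, scenario runs and patch-size sweeps.

The accuracy metric is the relative root-sum-square error
||L2|| = sqrt( sum_j (e_j - c_j)^2 / sum_j e_j^2 ) over the interior nodes,
with the reference e either an analytic series solution (linear model) or a
fine-step ETDRK4 run on the same spatial grid (nonlinear model, where no
closed form exists).  Wall-clock times are logged for the cost-vs-accuracy
comparison but are hardware-dependent and never asserted.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .discretize import GridSpec, build_grid, assemble_system
from .etd import SCHEMES, SimulationResult, integrate
from .model import InitialCondition, KissModel, catalog_ic

__all__ = [
    "l2_error",
    "ScenarioSpec",
    "run_scenario",
    "convergence_study",
    "patch_size_sweep",
    "test1_problem",
]


def l2_error(e: np.ndarray, c: np.ndarray) -> float:
    """Relative L2 error sqrt(sum (e-c)^2 / sum e^2) between reference e
    and computed c, elementwise over the solution vector."""
    ea = np.asarray(e, dtype=float).ravel()
    ca = np.asarray(c, dtype=float).ravel()
    if ea.shape != ca.shape:
        raise ValueError(f"shape mismatch: reference {ea.shape} vs computed {ca.shape}")
    denom = float(np.sum(ea**2))
    if denom == 0.0:
        raise ValueError("reference vector has zero norm")
    return math.sqrt(float(np.sum((ea - ca) ** 2)) / denom)


@dataclass(frozen=True)
class ScenarioSpec:
    """A complete simulation setup: physics, grid, initial data, stepping."""

    model: KissModel
    grid: GridSpec
    ic: InitialCondition | str
    k: float
    T: float
    scheme: str = "ETDRK4"
    disc: str = "fd4"
    snapshot_times: tuple[float, ...] | None = None
    ic_params: dict = field(default_factory=dict)

    def resolve_ic(self) -> InitialCondition:
        if isinstance(self.ic, str):
            return catalog_ic(self.ic, self.ic_params)
        return self.ic


def test1_problem(N: int = 200) -> ScenarioSpec:
    """The 1-D nonlinear benchmark: D = tau = 0.5, alpha = 2 on [-1, 1]
    with u0 = sin(2 pi x), absorbing boundaries, T = 1."""
    return ScenarioSpec(
        model=KissModel(D=0.5, tau=0.5, alpha=2.0),
        grid=GridSpec(dim=1, lo=-1.0, hi=1.0, N=N, bc="dirichlet0"),
        ic="sin2pix",
        k=1.0 / 256,
        T=1.0,
    )


def run_scenario(
    spec: ScenarioSpec,
    outdir=None,
    render: bool = False,
    **integrate_kw,
) -> SimulationResult:
    """Integrate one scenario; optionally write snapshots and render figures.

    Snapshot times must lie on the time-step grid (rejected otherwise).
    Rendered figures are qualitative profile/surface plots only.
    """
    if spec.scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {spec.scheme!r}; choose from {sorted(SCHEMES)}")
    grid = build_grid(spec.grid)
    system = assemble_system(spec.model, grid, disc=spec.disc)
    ic = spec.resolve_ic()
    result = integrate(
        system,
        ic,
        spec.T,
        spec.k,
        scheme=spec.scheme,
        snapshot_times=spec.snapshot_times,
        **integrate_kw,
    )
    result.meta.update(system.meta)
    result.meta["ic"] = ic.name
    if outdir is not None:
        from .output import write_result

        write_result(result, _spec_echo(spec), outdir, grid=grid)
    if render and outdir is not None:
        _render(result, grid, outdir)
    return result


def _spec_echo(spec: ScenarioSpec) -> dict:
    ic = spec.ic if isinstance(spec.ic, str) else spec.ic.name
    return {
        "model": {"D": spec.model.D, "tau": spec.model.tau, "alpha": spec.model.alpha},
        "domain": {
            "dim": spec.grid.dim,
            "lo": spec.grid.lo,
            "hi": spec.grid.hi,
            "N": spec.grid.N,
            "bc": spec.grid.bc,
        },
        "disc": spec.disc,
        "ic": {"name": ic, "params": dict(spec.ic_params)},
        "time": {"scheme": spec.scheme, "k": spec.k, "T": spec.T},
    }


def _render(result: SimulationResult, grid, outdir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(outdir)
    if grid.dim == 1:
        (x,) = grid.meshgrid(interior=True)
        fig, ax = plt.subplots()
        for t, u in zip(result.times, result.snapshots):
            ax.plot(x, u, label=f"t={t:g}")
        ax.set_xlabel("x")
        ax.set_ylabel("u(x,t)")
        ax.legend(fontsize="small")
        fig.savefig(out / "profiles.png", dpi=120)
        plt.close(fig)
    else:
        X, Y = grid.meshgrid(interior=True)
        for i, (t, u) in enumerate(zip(result.times, result.snapshots)):
            fig, ax = plt.subplots()
            m = ax.pcolormesh(X, Y, u, shading="auto")
            fig.colorbar(m, ax=ax)
            ax.set_title(f"t = {t:g}")
            fig.savefig(out / f"surface_{i:04d}.png", dpi=120)
            plt.close(fig)


# ---------------------------------------------------------------------------
# convergence / accuracy study
# ---------------------------------------------------------------------------


def convergence_study(
    problem: ScenarioSpec,
    schemes: Sequence[str] = ("ETDRK4",),
    ks: Sequence[float] = (1 / 32, 1 / 64, 1 / 256, 1 / 1024),
    reference: str | Callable[[np.ndarray], np.ndarray] = "self",
    k_ref: float = 1.0 / 8192,
    csv_path=None,
) -> pd.DataFrame:
    """Error table over (scheme, k) for one problem.

    ``reference``:
      * "self" -- ETDRK4 on the same spatial grid at step ``k_ref`` (the
        only option for the nonlinear model, which has no closed form);
      * a callable x -> u_exact(x, T) evaluated on the interior nodes
        (for the linear model with a series solution).

    Rows that blow up before T are flagged (l2 = NaN), never dropped.
    Wall time per run is logged in ``cpu_s``.
    """
    grid = build_grid(problem.grid)
    system = assemble_system(problem.model, grid, disc=problem.disc)
    u0 = grid.evaluate_ic(problem.resolve_ic())

    if callable(reference):
        coords = grid.meshgrid(interior=True)
        ref = np.asarray(reference(*coords), dtype=float)
        ref_desc = "analytic"
    elif reference == "self":
        res = integrate(system, u0, problem.T, k_ref, scheme="ETDRK4")
        if res.blowup:
            raise RuntimeError(f"reference run blew up at t={res.t_blowup}")
        ref = res.final
        ref_desc = f"ETDRK4@k={k_ref:g}"
    else:
        raise ValueError(f"unknown reference policy {reference!r}")

    rows = []
    for scheme in schemes:
        for k in ks:
            t0 = time.perf_counter()
            res = integrate(system, u0, problem.T, k, scheme=scheme)
            wall = time.perf_counter() - t0
            err = math.nan if res.blowup else l2_error(ref, res.final)
            rows.append(
                {
                    "method": scheme,
                    "k": k,
                    "l2": err,
                    "cpu_s": wall,
                    "blowup": res.blowup,
                    "reference": ref_desc,
                }
            )
    table = pd.DataFrame(rows)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    return table


def fitted_order(table: pd.DataFrame, method: str = "ETDRK4") -> float:
    """Least-squares slope of log(l2) vs log(k) for one scheme."""
    sub = table[(table["method"] == method) & np.isfinite(table["l2"])]
    if len(sub) < 2:
        raise ValueError("need at least two finite error rows to fit an order")
    return float(np.polyfit(np.log(sub["k"]), np.log(sub["l2"]), 1)[0])


# ---------------------------------------------------------------------------
# critical patch size sweep
# ---------------------------------------------------------------------------


def patch_size_sweep(
    model: KissModel,
    l_values: Sequence[float],
    T: float = 5.0,
    k: float = 1e-3,
    N: int = 200,
    scheme: str = "ETDRK4",
    disc: str = "fd4",
) -> tuple[pd.DataFrame, float]:
    """Empirical growth/decay threshold of the linear model vs patch size.

    For each patch length l the linear (alpha = 1) model is integrated on
    [0, l] from the slowest sine mode u0 = sin(pi x / l); the growth
    indicator is log(max|u(T)| / max|u(0)|) / T, whose analytic value is
    tau - D pi^2 / l^2.  The threshold estimate interpolates the indicator
    linearly in 1/l^2 across the sign-change bracket (exact for the
    analytic rate); NaN if no sign change occurs in the sweep.
    """
    if model.tau <= 0:
        raise ValueError("patch_size_sweep requires tau > 0")
    if model.alpha != 1.0:
        model = replace(model, alpha=1.0)
    rows = []
    for l in l_values:
        grid = build_grid(GridSpec(dim=1, lo=0.0, hi=float(l), N=N, bc="dirichlet0"))
        system = assemble_system(model, grid, disc=disc)
        u0 = np.sin(math.pi * grid.interior_axes()[0] / l)
        res = integrate(system, u0, T, k, scheme=scheme)
        rate = math.nan
        if not res.blowup:
            m0 = float(np.abs(res.snapshots[0]).max())
            mT = float(np.abs(res.final).max())
            rate = math.log(mT / m0) / T
        rows.append({"l": float(l), "indicator": rate, "blowup": res.blowup})
    table = pd.DataFrame(rows).sort_values("l", ignore_index=True)

    threshold = math.nan
    g = table["indicator"].to_numpy()
    ls = table["l"].to_numpy()
    for i in range(len(ls) - 1):
        if np.isfinite(g[i]) and np.isfinite(g[i + 1]) and g[i] < 0 <= g[i + 1]:
            s1, s2 = 1.0 / ls[i] ** 2, 1.0 / ls[i + 1] ** 2
            # rate is affine in s = 1/l^2: root by linear interpolation
            s_star = s1 - g[i] * (s2 - s1) / (g[i + 1] - g[i])
            threshold = 1.0 / math.sqrt(s_star)
            break
    table.attrs["threshold_estimate"] = threshold
    return table, threshold
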