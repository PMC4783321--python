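"""Run configuration: a small, versioned YAML schema validated up front.

Every field is checked against the owning module's preconditions before any
computation starts; unknown keys are rejected with their full key path.
All numeric defaults live in :data:`DEFAULTS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .discretize import GridSpec
from .etd import SCHEMES
from .experiments import ScenarioSpec
from .model import CATALOG, KissModel

__all__ = ["RunConfig", "load_config", "DEFAULTS"]

DEFAULTS = {
    "config_version": 1,
    "disc": "fd4",
    "ic": {"name": "sin2pix", "params": {}},
    "time": {"scheme": "ETDRK4"},
    "output": {"dir": "out", "formats": ["txt"]},
    "numerics": {
        "contour_points": 32,
        "contour_cutoff": 0.5,
        "blowup_threshold": 1e10,
        "reference_k": 1.0 / 8192,
    },
}

_SCHEMA = {
    "config_version": None,
    "model": {"D": None, "tau": None, "alpha": None},
    "domain": {"dim": None, "lo": None, "hi": None, "N": None, "bc": None},
    "disc": None,
    "ic": {"name": None, "params": None, "file": None},
    "time": {"scheme": None, "k": None, "T": None, "snapshot_times": None},
    "output": {"dir": None, "formats": None},
    "numerics": {
        "contour_points": None,
        "contour_cutoff": None,
        "blowup_threshold": None,
        "reference_k": None,
    },
}


class ConfigError(ValueError):
    """A configuration field failed validation; the message names the key
    path and the expected domain."""


def _check_keys(data: dict, schema: dict, path: str = "") -> None:
    for key, val in data.items():
        here = f"{path}.{key}" if path else key
        if key not in schema:
            raise ConfigError(
                f"unknown config key {here!r}; allowed at this level: "
                f"{sorted(schema)}"
            )
        if isinstance(schema[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here!r} must be a mapping")
            _check_keys(val, schema[key], here)


def _require(data: dict, section: str, key: str):
    try:
        return data[section][key]
    except (KeyError, TypeError):
        raise ConfigError(f"missing required config key {section}.{key!r}") from None


@dataclass(frozen=True)
class RunConfig:
    """Fully validated simulation configuration."""

    model: KissModel
    domain: GridSpec
    disc: str
    ic_name: str
    ic_params: dict
    ic_file: str | None
    scheme: str
    k: float
    T: float
    snapshot_times: tuple[float, ...] | None
    output_dir: str
    output_formats: tuple[str, ...]
    numerics: dict = field(default_factory=dict)

    def echo(self) -> dict:
        """Resolved configuration (defaults filled) for run metadata."""
        return {
            "config_version": 1,
            "model": {"D": self.model.D, "tau": self.model.tau,
                      "alpha": self.model.alpha},
            "domain": {"dim": self.domain.dim, "lo": self.domain.lo,
                       "hi": self.domain.hi, "N": self.domain.N,
                       "bc": self.domain.bc},
            "disc": self.disc,
            "ic": {"name": self.ic_name, "params": self.ic_params,
                   "file": self.ic_file},
            "time": {"scheme": self.scheme, "k": self.k, "T": self.T,
                     "snapshot_times": list(self.snapshot_times)
                     if self.snapshot_times else None},
            "output": {"dir": self.output_dir,
                       "formats": list(self.output_formats)},
            "numerics": dict(self.numerics),
        }

    def to_scenario(self) -> ScenarioSpec:
        from .model import catalog_ic, load_ic_file

        if self.ic_file is not None:
            from .discretize import build_grid

            ic = load_ic_file(self.ic_file, grid=build_grid(self.domain))
        else:
            ic = catalog_ic(self.ic_name, self.ic_params)
        return ScenarioSpec(
            model=self.model,
            grid=self.domain,
            ic=ic,
            k=self.k,
            T=self.T,
            scheme=self.scheme,
            disc=self.disc,
            snapshot_times=self.snapshot_times,
        )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, _SCHEMA)

    version = raw.get("config_version", DEFAULTS["config_version"])
    if version != 1:
        raise ConfigError(f"config_version must be 1, got {version!r}")

    D = _require(raw, "model", "D")
    tau = _require(raw, "model", "tau")
    alpha = raw["model"].get("alpha", 1.0)
    try:
        model = KissModel(D=float(D), tau=float(tau), alpha=float(alpha))
    except ValueError as exc:
        raise ConfigError(f"model: {exc}") from None

    dom = raw.get("domain")
    if not isinstance(dom, dict):
        raise ConfigError("missing required section 'domain'")
    try:
        domain = GridSpec(
            dim=int(dom.get("dim", 1)),
            lo=float(_require(raw, "domain", "lo")),
            hi=float(_require(raw, "domain", "hi")),
            N=int(_require(raw, "domain", "N")),
            bc=dom.get("bc", "dirichlet0"),
        )
    except ValueError as exc:
        raise ConfigError(f"domain: {exc}") from None

    disc = raw.get("disc", DEFAULTS["disc"])
    if disc not in ("fd4", "spectral"):
        raise ConfigError(f"disc must be 'fd4' or 'spectral', got {disc!r}")

    ic = raw.get("ic", DEFAULTS["ic"])
    ic_file = ic.get("file")
    ic_name = ic.get("name", DEFAULTS["ic"]["name"])
    ic_params = ic.get("params") or {}
    if ic_file is None and ic_name not in CATALOG:
        raise ConfigError(
            f"ic.name {ic_name!r} not in catalog {sorted(CATALOG)}"
        )

    tsec = raw.get("time")
    if not isinstance(tsec, dict):
        raise ConfigError("missing required section 'time'")
    scheme = tsec.get("scheme", DEFAULTS["time"]["scheme"])
    if scheme not in SCHEMES:
        raise ConfigError(f"time.scheme {scheme!r} not one of {sorted(SCHEMES)}")
    k = float(_require(raw, "time", "k"))
    T = float(_require(raw, "time", "T"))
    if k <= 0 or T <= 0:
        raise ConfigError("time.k and time.T must be > 0")
    ratio = T / k
    if abs(ratio - round(ratio)) > 1e-8 * max(1.0, round(ratio)) or round(ratio) < 1:
        raise ConfigError(
            f"time.T/time.k = {ratio} must be a whole number of steps"
        )
    snaps = tsec.get("snapshot_times")
    snapshot_times = tuple(float(s) for s in snaps) if snaps else None

    out = {**DEFAULTS["output"], **(raw.get("output") or {})}
    numerics = {**DEFAULTS["numerics"], **(raw.get("numerics") or {})}
    if numerics["contour_points"] < 4:
        raise ConfigError("numerics.contour_points must be >= 4")
    if not (0 < numerics["contour_cutoff"] <= 2.0):
        raise ConfigError("numerics.contour_cutoff must lie in (0, 2]")

    return RunConfig(
        model=model,
        domain=domain,
        disc=disc,
        ic_name=ic_name,
        ic_params=dict(ic_params),
        ic_file=ic_file,
        scheme=scheme,
        k=k,
        T=T,
        snapshot_times=snapshot_times,
        output_dir=str(out["dir"]),
        output_formats=tuple(out["formats"]),
        numerics=numerics,
    )
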