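"""Scenario configuration: YAML schema, validation, and the scenario runner.

A scenario bundles a circuit model (inline or preset), what to run (PDE,
reduced ODE, or both), grid/time settings, and output paths.  Re-running a
scenario with the same config reproduces its output tables bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuits import (
    ClockParams,
    RepressorParams,
    TxTlParams,
    detect_oscillations,
    simulate_clock,
    simulate_repressor,
    txtl_model,
)
from .network import CircuitModel
from .pde import SpatialGrid, simulate_pde
from .reduced import resolve_thetas, simulate_reduced

logger = logging.getLogger(__name__)

__all__ = ["Scenario", "ConfigError", "load_scenario", "run_scenario", "builtin_scenario"]


class ConfigError(ValueError):
    """Invalid scenario configuration; the message names the offending field."""


_RUN_MODES = {"pde", "ode", "both"}
_MODEL_KINDS = {"circuit", "txtl", "repressor", "clock"}


@dataclass
class Scenario:
    name: str
    model_kind: str               # circuit | txtl | repressor | clock
    model: object                 # CircuitModel or a params dataclass
    run: str = "ode"
    grid: int = 200
    t_end: float = 10.0
    theta: object = "auto"
    seed: int = 0
    clock_mode: str = "qssa"
    extras: dict = field(default_factory=dict)


def _require(cfg: dict, key: str, ctx: str):
    if key not in cfg:
        raise ConfigError(f"missing required field '{ctx}{key}'")
    return cfg[key]


def load_scenario(source) -> Scenario:
    """Load and validate a scenario from a YAML path, text, or dict."""
    if isinstance(source, dict):
        cfg = source
    else:
        try:
            is_file = Path(str(source)).exists()
        except OSError:  # e.g. YAML text too long to be a path
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("scenario config must be a mapping")

    name = str(cfg.get("name", "scenario"))
    run = str(cfg.get("run", "ode"))
    if run not in _RUN_MODES:
        raise ConfigError(f"field 'run' must be one of {sorted(_RUN_MODES)}, got {run!r}")

    model_cfg = _require(cfg, "model", "")
    if not isinstance(model_cfg, dict):
        raise ConfigError("field 'model' must be a mapping")
    kind = str(model_cfg.get("kind", "circuit"))
    if kind not in _MODEL_KINDS:
        raise ConfigError(f"field 'model.kind' must be one of {sorted(_MODEL_KINDS)}")
    params = model_cfg.get("params", {})
    try:
        if kind == "circuit":
            model: object = CircuitModel.from_dict(model_cfg)
        elif kind == "txtl":
            model = TxTlParams(**params)
        elif kind == "repressor":
            model = RepressorParams(**params)
        else:
            model = ClockParams(**params)
    except (TypeError, ValueError, KeyError) as exc:
        raise ConfigError(f"invalid 'model' section: {exc}") from exc

    if kind in {"repressor", "clock"} and run != "ode":
        raise ConfigError(f"model.kind={kind!r} supports run: ode only")

    return Scenario(
        name=name,
        model_kind=kind,
        model=model,
        run=run,
        grid=int(cfg.get("grid", 200)),
        t_end=float(cfg.get("t_end", 10.0)),
        theta=cfg.get("theta", "auto"),
        seed=int(cfg.get("seed", 0)),
        clock_mode=str(cfg.get("clock_mode", "qssa")),
        extras=dict(cfg.get("extras", {})),
    )


def builtin_scenario(name: str) -> Scenario:
    """Load one of the shipped scenario fixtures by name (e.g. "fig5a")."""
    ref = resources.files("spatialcircuits.scenarios").joinpath(f"{name}.yaml")
    return load_scenario(yaml.safe_load(ref.read_text()))


def _as_circuit(scenario: Scenario) -> CircuitModel:
    if scenario.model_kind == "circuit":
        return scenario.model  # type: ignore[return-value]
    if scenario.model_kind == "txtl":
        return txtl_model(scenario.model)  # type: ignore[arg-type]
    raise ConfigError(f"model.kind={scenario.model_kind!r} has no spatial circuit form")


def _compare(averages_a: dict, averages_b: dict) -> pd.DataFrame:
    rows = []
    for name in averages_a:
        a = np.asarray(averages_a[name])
        b = np.asarray(averages_b[name])
        scale = max(np.abs(a).max(), np.abs(b).max())
        sup = float(np.abs(a - b).max())
        rows.append(
            {
                "species": name,
                "sup_abs_diff": sup,
                "sup_rel_diff": sup / scale if scale > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def run_scenario(scenario: Scenario, out_dir: str | Path | None = None) -> dict:
    """Execute a scenario and return (optionally write) its artifacts.

    Artifacts: tidy averages tables per executed model, a JSON-able summary
    (θ* values, steady values, oscillation report, comparison metrics), and
    for run=both a per-species comparison table of PDE vs reduced averages.
    """
    logger.info("running scenario %s (kind=%s, run=%s)", scenario.name, scenario.model_kind, scenario.run)
    artifacts: dict = {"name": scenario.name, "summary": {"name": scenario.name}}

    if scenario.model_kind in {"circuit", "txtl"}:
        model = _as_circuit(scenario)
        thetas = resolve_thetas(model, scenario.theta)
        artifacts["summary"]["theta"] = thetas
        n_saves = 201
        if scenario.run in {"ode", "both"}:
            ode = simulate_reduced(model, theta=scenario.theta, t_end=scenario.t_end, n_saves=n_saves)
            artifacts["ode"] = ode
            artifacts["ode_averages"] = ode.averages_frame()
            artifacts["summary"]["ode_final"] = {k: float(v[-1]) for k, v in ode.averages.items()}
        if scenario.run in {"pde", "both"}:
            pde = simulate_pde(
                model, grid=SpatialGrid(scenario.grid), t_end=scenario.t_end, n_saves=n_saves
            )
            artifacts["pde"] = pde
            artifacts["pde_averages"] = pde.averages_frame()
            artifacts["summary"]["pde_final"] = {k: float(v[-1]) for k, v in pde.averages.items()}
        if scenario.run == "both":
            shared = [k for k in artifacts["ode"].averages if k in artifacts["pde"].averages]
            comparison = _compare(
                {k: artifacts["pde"].averages[k] for k in shared},
                {k: artifacts["ode"].averages[k] for k in shared},
            )
            artifacts["comparison"] = comparison
            artifacts["summary"]["max_rel_diff"] = float(comparison["sup_rel_diff"].max())
    elif scenario.model_kind == "repressor":
        t, traj = simulate_repressor(scenario.model, theta=scenario.theta, t_end=scenario.t_end)
        artifacts["ode_averages"] = pd.concat(
            [pd.DataFrame({"time": t, "species": k, "average": v}) for k, v in traj.items()],
            ignore_index=True,
        )
        artifacts["summary"]["ode_final"] = {k: float(v[-1]) for k, v in traj.items()}
    else:  # clock
        t, traj = simulate_clock(scenario.model, mode=scenario.clock_mode, t_end=scenario.t_end)
        artifacts["ode_averages"] = pd.concat(
            [pd.DataFrame({"time": t, "species": k, "average": v}) for k, v in traj.items()],
            ignore_index=True,
        )
        rep = detect_oscillations(t, traj["Pa"])
        artifacts["summary"]["oscillation"] = {
            "oscillating": rep.oscillating,
            "amplitude": rep.amplitude,
            "period": rep.period,
            "n_peaks": rep.n_peaks,
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key in ("ode_averages", "pde_averages", "comparison"):
            if key in artifacts:
                artifacts[key].to_csv(out / f"{scenario.name}_{key}.csv", index=False)
        if "pde" in artifacts and scenario.extras.get("save_fields"):
            artifacts["pde"].fields_frame().to_csv(
                out / f"{scenario.name}_fields.csv", index=False
            )
        (out / f"{scenario.name}_summary.json").write_text(
            json.dumps(artifacts["summary"], indent=2, default=float)
        )
    return artifacts
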