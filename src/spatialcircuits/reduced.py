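"""Reduced space-averaged ODE model with constant binding correction factors.

The reduced model has exactly the dimension of the well-mixed ODE model: one
state per species (and per complex).  The only difference from the
well-mixed equations is that each association rate aᵢ is multiplied by its
BCF θᵢ*; setting every θᵢ* = 1 recovers the well-mixed model identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .bcf import bcf_case1, bcf_fixed
from .geometry import available_volume
from .network import CircuitModel, classify_case
from .pde import IntegrationFailure

__all__ = [
    "ReducedState",
    "ReducedTrajectory",
    "resolve_thetas",
    "simulate_reduced",
    "simulate_well_mixed",
    "steady_state",
    "find_steady_state",
    "NoSteadyStateError",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class NoSteadyStateError(RuntimeError):
    """No stable steady state was found (e.g. an oscillatory regime)."""


@dataclass(frozen=True)
class ReducedState:
    """Space-averaged steady state: concentrations per species plus the θ* used."""

    averages: dict[str, float]
    thetas: dict[str, float] = field(default_factory=dict)
    residual: float = 0.0

    def __getitem__(self, name: str) -> float:
        return self.averages[name]


@dataclass
class ReducedTrajectory:
    times: np.ndarray
    averages: dict[str, np.ndarray]
    thetas: dict[str, float] = field(default_factory=dict)

    def averages_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame({"time": self.times, "species": name, "average": avg})
            for name, avg in self.averages.items()
        ]
        return pd.concat(rows, ignore_index=True)


def resolve_thetas(model: CircuitModel, theta="auto") -> dict[str, float]:
    """Per-reaction θ* keyed by complex name.

    ``theta`` may be "auto" (compute from the mobility case), a scalar
    applied to every reaction, or a mapping {complex name: value}.
    """
    names = [r.complex_name for r in model.reactions]
    if isinstance(theta, str) and theta == "auto":
        out = {}
        for rxn in model.reactions:
            case = classify_case(rxn, model)
            E, S = model.spec(rxn.enzyme), model.spec(rxn.substrate)
            vE = available_volume(model.density, E.r_rel)
            vS = available_volume(model.density, S.r_rel)
            if case == "I":
                out[rxn.complex_name] = bcf_case1(vE, vS).value
            elif case == "II":
                out[rxn.complex_name] = bcf_fixed(vS, E.mobility.x_star).value
            else:
                out[rxn.complex_name] = bcf_fixed(vE, S.mobility.x_star).value
        return out
    if isinstance(theta, Mapping):
        missing = set(names) - set(theta)
        if missing:
            raise ValueError(f"missing theta for reactions {sorted(missing)}")
        vals = {k: float(theta[k]) for k in names}
    else:
        vals = {k: float(theta) for k in names}
    if any(v <= 0 for v in vals.values()):
        raise ValueError("theta values must be > 0")
    return vals


def _reduced_rhs(model: CircuitModel, thetas: dict[str, float]):
    specs = list(model.species) + [model.complex_spec(r) for r in model.reactions]
    idx = {sp.name: k for k, sp in enumerate(specs)}
    # complexes carry no generic loss: all their channels live in d_tilde
    n_declared = len(model.species)
    loss = np.array(
        [
            0.0 if (sp.conserved or k >= n_declared) else sp.gamma + 1.0
            for k, sp in enumerate(specs)
        ]
    )
    prods = []
    for name, p in model.productions.items():
        if model.spec(name).conserved:
            raise ValueError(f"conserved species {name!r} cannot be produced")
        prods.append((idx[name], p))
    rxn_data = []
    for rxn in model.reactions:
        E, S = model.spec(rxn.enzyme), model.spec(rxn.substrate)
        ret_E = S.gamma + rxn.d + rxn.kappa + (1.0 if E.conserved else 0.0)
        ret_S = E.gamma + rxn.d + rxn.kappa + (1.0 if S.conserved else 0.0)
        rxn_data.append(
            (idx[rxn.enzyme], idx[rxn.substrate], idx[rxn.complex_name],
             idx[rxn.product] if rxn.product is not None else None,
             rxn.a * thetas[rxn.complex_name], ret_E, ret_S,
             rxn.d_tilde(E.gamma, S.gamma), rxn.kappa)
        )

    def rhs(t, y):
        dy = -loss * y
        for k, p in prods:
            dy[k] += p.rate(t)
        for kE, kS, kC, kP, a_eff, ret_E, ret_S, dtil, kappa in rxn_data:
            rate = a_eff * y[kE] * y[kS]
            c = y[kC]
            dy[kE] += -rate + ret_E * c
            dy[kS] += -rate + ret_S * c
            dy[kC] += rate - dtil * c
            if kP is not None:
                dy[kP] += kappa * c
        return dy

    y0 = np.array([sp.initial_total for sp in specs])
    return rhs, [sp.name for sp in specs], y0


def simulate_reduced(
    model: CircuitModel,
    theta="auto",
    t_end: float = 10.0,
    y0: Mapping[str, float] | None = None,
    n_saves: int = 201,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    t_eval: np.ndarray | None = None,
) -> ReducedTrajectory:
    """Integrate the reduced space-averaged model (θ* = 1 gives well-mixed)."""
    thetas = resolve_thetas(model, theta)
    rhs, names, y0_vec = _reduced_rhs(model, thetas)
    if y0 is not None:
        y0_vec = y0_vec.copy()
        for name, val in y0.items():
            y0_vec[names.index(name)] = float(val)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_saves)
    sol = solve_ivp(
        rhs, (0.0, float(t_end)), y0_vec, method="BDF", t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise IntegrationFailure(f"reduced ODE integration failed: {sol.message}")
    averages = {name: sol.y[k] for k, name in enumerate(names)}
    return ReducedTrajectory(times=sol.t, averages=averages, thetas=thetas)


def simulate_well_mixed(model: CircuitModel, **kwargs) -> ReducedTrajectory:
    """The standard well-mixed model: the reduced model with every θ* = 1."""
    return simulate_reduced(model, theta=1.0, **kwargs)


def find_steady_state(
    rhs, y0: np.ndarray, t_probe: float = 200.0, tol: float = 1e-10
) -> np.ndarray:
    """Locate a steady state of dy/dt = rhs(t, y) from the long-time endpoint,
    refined by (damped) Newton.

    Raises :class:`NoSteadyStateError` if the long-time trajectory keeps
    moving (sustained oscillations) or Newton fails to reach ``tol``.
    """
    sol = solve_ivp(rhs, (0.0, t_probe), np.asarray(y0, dtype=float), method="BDF",
                    rtol=1e-9, atol=1e-12, dense_output=True)
    if not sol.success:
        raise IntegrationFailure(f"probe integration failed: {sol.message}")
    # compare endpoint against the trailing quarter of the trajectory
    tail_t = np.linspace(0.75 * t_probe, t_probe, 50)
    tail = sol.sol(tail_t)
    scale = max(1.0, float(np.abs(tail).max()))
    drift = float(np.abs(tail - tail[:, -1:]).max()) / scale
    if drift > 1e-3:
        raise NoSteadyStateError(
            f"trajectory endpoint still moving (relative drift {drift:.2e}); "
            "possibly an oscillatory regime"
        )
    res = root(lambda y: rhs(0.0, y), sol.y[:, -1], method="hybr", tol=1e-13)
    y_ss = res.x
    resid = float(np.abs(rhs(0.0, y_ss)).max())
    if not res.success or resid > tol:
        raise NoSteadyStateError(f"Newton refinement failed (residual {resid:.2e})")
    return y_ss


def steady_state(model: CircuitModel, theta="auto", t_probe: float = 200.0) -> ReducedState:
    """Steady state of the reduced model for a time-invariant circuit."""
    for name, p in model.productions.items():
        if callable(p.alpha_bar):
            raise ValueError(f"production of {name!r} is time-varying: model not autonomous")
    thetas = resolve_thetas(model, theta)
    rhs, names, y0 = _reduced_rhs(model, thetas)
    y_ss = find_steady_state(rhs, y0, t_probe=t_probe)
    resid = float(np.abs(rhs(0.0, y_ss)).max())
    return ReducedState(
        averages={name: float(v) for name, v in zip(names, y_ss)},
        thetas=thetas,
        residual=resid,
    )
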