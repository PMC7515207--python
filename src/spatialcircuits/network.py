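"""Declarative description of enzymatic-like binding circuits.

A :class:`CircuitModel` lists species (with radius ratios, mobility and
degradation), 1:1 binding reactions E + S ⇌ c → P + E + S, and production
terms.  Each reaction is automatically classified by the mobility of its
pair:

    Case I   — both diffuse           (e.g. mRNA binding ribosomes)
    Case II  — enzyme fixed           (e.g. RNAP binding a gene; enzyme = gene)
    Case III — substrate fixed        (e.g. a TF dimer binding a promoter)

All rates are dimensionless: time in units of the dilution rate μ,
concentrations per unit length scaled by μ/a₁, lengths by the half-cell L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .geometry import ChromosomeDensity, density_from_dict, logistic_density

__all__ = [
    "Diffusing",
    "Fixed",
    "SpeciesSpec",
    "BindingReaction",
    "Production",
    "CircuitModel",
    "localized_production",
    "localized_profile",
    "classify_case",
    "UnsupportedCaseError",
]

DEFAULT_DELTA = 0.02
DEFAULT_EPSILON = 1e-3


class UnsupportedCaseError(ValueError):
    """Raised for a binding pair in which both species are spatially fixed."""


@dataclass(frozen=True)
class Diffusing:
    """Freely diffusing mobility; ``chi`` is D/D_ref relative to the reference species."""

    chi: float = 1.0

    def __post_init__(self):
        if not self.chi > 0:
            raise ValueError(f"chi must be > 0, got {self.chi}")


@dataclass(frozen=True)
class Fixed:
    """Spatially fixed at ``x_star`` with localization half-width ``delta``."""

    x_star: float
    delta: float = DEFAULT_DELTA

    def __post_init__(self):
        if not 0.0 <= self.x_star <= 1.0:
            raise ValueError(f"x_star must lie in [0, 1], got {self.x_star}")
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"delta must lie in (0, 1), got {self.delta}")


@dataclass(frozen=True)
class SpeciesSpec:
    """One chemical species.

    ``gamma`` is the degradation rate (dilution at rate 1 is always added on
    top for non-conserved species).  ``conserved`` marks species whose total
    (free + complexed) is held constant, as for gene DNA whose copy number is
    maintained through growth: the species is neither produced, degraded nor
    diluted, and every loss channel of its complexes returns it.
    ``initial_total`` seeds the initial condition (distributed per the
    localization profile for fixed species, uniformly for diffusing ones).
    """

    name: str
    r_rel: float = 0.0
    mobility: Diffusing | Fixed = field(default_factory=Diffusing)
    gamma: float = 0.0
    conserved: bool = False
    initial_total: float = 0.0

    def __post_init__(self):
        if self.r_rel < 0:
            raise ValueError(f"{self.name}: r_rel must be >= 0")
        if self.gamma < 0:
            raise ValueError(f"{self.name}: gamma must be >= 0")

    @property
    def is_fixed(self) -> bool:
        return isinstance(self.mobility, Fixed)


@dataclass(frozen=True)
class BindingReaction:
    """E + S ⇌(a, d) c →(kappa) P + E + S with optional catalytic product P.

    Derived quantities: the lumped complex loss rate d̃ = γE + γS + d + κ + 1
    and the binding time-scale parameter η = 1/d̃ (η ≪ 1 means fast binding).
    ``chi_complex`` overrides the complex's diffusion ratio, which defaults
    to min(χE, χS) — a complex diffuses no faster than its slowest parent.
    """

    enzyme: str
    substrate: str
    a: float
    d: float = 0.0
    kappa: float = 0.0
    product: str | None = None
    chi_complex: float | None = None

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError("association rate a must be > 0")
        if self.d < 0 or self.kappa < 0:
            raise ValueError("d and kappa must be >= 0")

    @property
    def complex_name(self) -> str:
        return f"{self.enzyme}:{self.substrate}"

    def d_tilde(self, gammaE: float, gammaS: float) -> float:
        return gammaE + gammaS + self.d + self.kappa + 1.0

    def eta(self, gammaE: float, gammaS: float) -> float:
        return 1.0 / self.d_tilde(gammaE, gammaS)


def localized_profile(
    x_star: float, delta: float, shape: str = "tophat"
) -> Callable[[np.ndarray], np.ndarray]:
    """Unit-mass spatial profile localized at x* with half-width δ.

    The default is a top-hat on [x*−δ, x*+δ] ∩ [0, 1], renormalized exactly
    after boundary clipping so that ∫₀¹ profile dx = 1 independent of δ (the
    total DNA of a localized gene does not depend on how tightly it is
    confined).  ``shape="gaussian"`` gives a truncated Gaussian with
    standard deviation δ/2 for smoothness studies.
    """
    if not 0.0 <= x_star <= 1.0:
        raise ValueError(f"x_star must lie in [0, 1], got {x_star}")
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    lo, hi = max(0.0, x_star - delta), min(1.0, x_star + delta)
    if hi <= lo:
        raise ValueError("empty localization window after clipping to [0, 1]")

    if shape == "tophat":
        height = 1.0 / (hi - lo)

        def profile(x):
            x = np.asarray(x, dtype=float)
            return np.where((x >= lo) & (x <= hi), height, 0.0)

        return profile

    if shape == "gaussian":
        from scipy.stats import norm

        sigma = delta / 2.0
        zmass = norm.cdf(1.0, loc=x_star, scale=sigma) - norm.cdf(0.0, loc=x_star, scale=sigma)

        def profile(x):
            x = np.asarray(x, dtype=float)
            return norm.pdf(x, loc=x_star, scale=sigma) / zmass

        return profile

    raise ValueError(f"unknown profile shape {shape!r}")


def localized_production(
    x_star: float, delta: float, alpha_bar: float, shape: str = "tophat"
) -> Callable[[np.ndarray], np.ndarray]:
    """Production-rate profile α(x) localized at x* with exact mass ᾱ = ``alpha_bar``."""
    if alpha_bar < 0:
        raise ValueError(f"alpha_bar must be >= 0, got {alpha_bar}")
    if alpha_bar == 0.0:
        return lambda x: np.zeros_like(np.asarray(x, dtype=float))
    base = localized_profile(x_star, delta, shape)
    return lambda x: alpha_bar * base(x)


@dataclass(frozen=True)
class Production:
    """Space-averaged production rate ᾱ(t) with a spatial profile.

    ``alpha_bar`` is a constant or a callable of dimensionless time.  With
    ``x_star`` unset the profile is uniform; otherwise it is localized via
    :func:`localized_profile` (mass-preserving regardless of δ).
    """

    alpha_bar: float | Callable[[float], float]
    x_star: float | None = None
    delta: float = DEFAULT_DELTA
    shape: str = "tophat"

    def rate(self, t: float) -> float:
        return float(self.alpha_bar(t)) if callable(self.alpha_bar) else float(self.alpha_bar)

    def spatial_profile(self) -> Callable[[np.ndarray], np.ndarray]:
        if self.x_star is None:
            return lambda x: np.ones_like(np.asarray(x, dtype=float))
        return localized_profile(self.x_star, self.delta, self.shape)


@dataclass
class CircuitModel:
    """A binding-reaction network with spatial attributes.

    ``epsilon`` = μL²/D is the diffusion time-scale ratio of the reference
    diffusing species (fast diffusion means ε ≪ 1).  Complex species are
    created automatically, one per reaction, with volume profile equal to
    the product of the parents' (r_c² = r_E² + r_S²) and mobility inherited
    per case: diffusing in Case I, fixed at the fixed parent's location in
    Cases II/III.
    """

    species: list[SpeciesSpec]
    reactions: list[BindingReaction] = field(default_factory=list)
    productions: dict[str, Production] = field(default_factory=dict)
    epsilon: float = DEFAULT_EPSILON
    density: ChromosomeDensity = field(default_factory=logistic_density)
    name: str = "circuit"

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        self._by_name = {s.name: s for s in self.species}
        for rxn in self.reactions:
            for role, sp in (("enzyme", rxn.enzyme), ("substrate", rxn.substrate)):
                if sp not in self._by_name:
                    raise ValueError(f"reaction references undeclared {role} {sp!r}")
            if rxn.product is not None and rxn.product not in self._by_name:
                raise ValueError(f"reaction references undeclared product {rxn.product!r}")
            if rxn.enzyme == rxn.substrate:
                raise ValueError("self-binding (enzyme == substrate) is not supported")
            classify_case(rxn, self)  # raises UnsupportedCaseError for two fixed partners
        for sp in self.productions:
            if sp not in self._by_name:
                raise ValueError(f"production for undeclared species {sp!r}")

    def spec(self, name: str) -> SpeciesSpec:
        return self._by_name[name]

    def complex_spec(self, rxn: BindingReaction) -> SpeciesSpec:
        """The auto-generated complex species of a reaction."""
        E, S = self.spec(rxn.enzyme), self.spec(rxn.substrate)
        r_rel = float(np.hypot(E.r_rel, S.r_rel))
        case = classify_case(rxn, self)
        if case == "I":
            chi = rxn.chi_complex
            if chi is None:
                chi = min(E.mobility.chi, S.mobility.chi)
            mobility: Diffusing | Fixed = Diffusing(chi=chi)
        else:
            fixed = E.mobility if E.is_fixed else S.mobility
            mobility = Fixed(x_star=fixed.x_star, delta=fixed.delta)
        return SpeciesSpec(name=rxn.complex_name, r_rel=r_rel, mobility=mobility, gamma=0.0)

    # --- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        def mob(m):
            if isinstance(m, Diffusing):
                return {"type": "diffusing", "chi": m.chi}
            return {"type": "fixed", "x_star": m.x_star, "delta": m.delta}

        return {
            "name": self.name,
            "epsilon": self.epsilon,
            "density": self.density.to_dict(),
            "species": [
                {
                    "name": s.name,
                    "r_rel": s.r_rel,
                    "mobility": mob(s.mobility),
                    "gamma": s.gamma,
                    "conserved": s.conserved,
                    "initial_total": s.initial_total,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "enzyme": r.enzyme,
                    "substrate": r.substrate,
                    "a": r.a,
                    "d": r.d,
                    "kappa": r.kappa,
                    "product": r.product,
                    "chi_complex": r.chi_complex,
                }
                for r in self.reactions
            ],
            "productions": {
                name: {
                    "alpha_bar": p.alpha_bar,
                    "x_star": p.x_star,
                    "delta": p.delta,
                    "shape": p.shape,
                }
                for name, p in self.productions.items()
                if not callable(p.alpha_bar)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitModel":
        def mob(m):
            if m.get("type", "diffusing") == "diffusing":
                return Diffusing(chi=float(m.get("chi", 1.0)))
            return Fixed(x_star=float(m["x_star"]), delta=float(m.get("delta", DEFAULT_DELTA)))

        species = [
            SpeciesSpec(
                name=s["name"],
                r_rel=float(s.get("r_rel", 0.0)),
                mobility=mob(s.get("mobility", {})),
                gamma=float(s.get("gamma", 0.0)),
                conserved=bool(s.get("conserved", False)),
                initial_total=float(s.get("initial_total", 0.0)),
            )
            for s in d["species"]
        ]
        reactions = [
            BindingReaction(
                enzyme=r["enzyme"],
                substrate=r["substrate"],
                a=float(r["a"]),
                d=float(r.get("d", 0.0)),
                kappa=float(r.get("kappa", 0.0)),
                product=r.get("product"),
                chi_complex=r.get("chi_complex"),
            )
            for r in d.get("reactions", [])
        ]
        productions = {
            name: Production(
                alpha_bar=float(p["alpha_bar"]),
                x_star=p.get("x_star"),
                delta=float(p.get("delta", DEFAULT_DELTA)),
                shape=p.get("shape", "tophat"),
            )
            for name, p in d.get("productions", {}).items()
        }
        return cls(
            species=species,
            reactions=reactions,
            productions=productions,
            epsilon=float(d.get("epsilon", DEFAULT_EPSILON)),
            density=density_from_dict(d.get("density", {"kind": "logistic"})),
            name=d.get("name", "circuit"),
        )

    def with_epsilon(self, epsilon: float) -> "CircuitModel":
        return replace(self, epsilon=epsilon)


def classify_case(reaction: BindingReaction, model: CircuitModel) -> str:
    """Mobility case of a binding pair: "I", "II" or "III" (see module docstring)."""
    E = model._by_name[reaction.enzyme]
    S = model._by_name[reaction.substrate]
    if E.is_fixed and S.is_fixed:
        raise UnsupportedCaseError(
            f"both {E.name} and {S.name} are fixed: no diffusing partner"
        )
    if not E.is_fixed and not S.is_fixed:
        return "I"
    return "II" if E.is_fixed else "III"
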