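"""Chromosome-density and available-volume profiles on the half-cell.

The cell is modeled as a cylinder of half-length L with axial coordinate
x ∈ [0, 1] after nondimensionalization (x = 0 mid-cell, x = 1 cell pole).
The chromosomal DNA mesh is described by a normalized density ρ̂(x) with
∫₀¹ ρ̂ dx = 1/2 (one half-cell carries half of the DNA).  A molecule with
radius of gyration r diffusing through the mesh sees the available-volume
fraction

    v(x) = exp(−(r/r*)² ρ̂(x)),

where r* is the exclusion length scale set by the total DNA length per
volume, (r*)² = Vp / (2 κ π Lp).  All radii in this package are supplied
as the dimensionless ratio r/r*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ChromosomeDensity",
    "VolumeProfile",
    "logistic_density",
    "step_density",
    "custom_density",
    "available_volume",
    "complex_volume",
    "normalize_profile",
    "r_star",
    "quadrature",
]

#: density mass on the half-cell: ∫₀¹ ρ̂ dx = 1/2
DENSITY_MASS = 0.5

_QUAD_POINTS = 2001  # composite-Simpson points per smooth piece (≥1001 per spec of the method)


def _simpson_piece(f: Callable[[np.ndarray], np.ndarray], a: float, b: float, n: int) -> float:
    if b <= a:
        return 0.0
    if n % 2 == 0:
        n += 1
    x = np.linspace(a, b, n)
    # sample endpoints just inside the piece: breakpoints mark jump
    # discontinuities, and the one-sided limit is the correct value here
    nudge = (b - a) * 1e-12
    x[0] += nudge
    x[-1] -= nudge
    y = np.asarray(f(x), dtype=float)
    h = (b - a) / (n - 1)
    return float(h / 3.0 * (y[0] + y[-1] + 4.0 * y[1:-1:2].sum() + 2.0 * y[2:-2:2].sum()))


def quadrature(
    f: Callable[[np.ndarray], np.ndarray],
    breakpoints: Sequence[float] = (),
    n: int = _QUAD_POINTS,
    check: bool = True,
    tol: float = 1e-8,
) -> float:
    """Integrate ``f`` over [0, 1] by composite Simpson, piecewise across breakpoints.

    ``breakpoints`` are interior discontinuity locations (e.g. the edge of a
    step density); integrating each smooth piece separately keeps Simpson at
    its full order.  With ``check`` a Richardson step (doubling n) verifies the
    result to ``tol`` and warns otherwise.
    """
    pts = sorted({0.0, 1.0, *(float(b) for b in breakpoints if 0.0 < float(b) < 1.0)})
    total = sum(_simpson_piece(f, a, b, n) for a, b in zip(pts[:-1], pts[1:]))
    if check:
        refined = sum(_simpson_piece(f, a, b, 2 * n) for a, b in zip(pts[:-1], pts[1:]))
        if abs(refined - total) > tol * max(1.0, abs(refined)):
            warnings.warn(
                f"quadrature did not converge to {tol:g} (delta={refined - total:g})",
                RuntimeWarning,
                stacklevel=2,
            )
        total = refined
    return total


@dataclass(frozen=True)
class ChromosomeDensity:
    """Normalized axial DNA-length density ρ̂(x) on the half-cell.

    Invariants: ρ̂ ≥ 0 and ∫₀¹ ρ̂ dx = 1/2.  Construct through
    :func:`logistic_density`, :func:`step_density` or :func:`custom_density`.
    """

    kind: str
    params: dict = field(compare=True)
    _fn: Callable[[np.ndarray], np.ndarray] = field(compare=False, repr=False)
    breakpoints: tuple = ()

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self._fn(x)

    def mass(self) -> float:
        """∫₀¹ ρ̂ dx, which is 1/2 by construction."""
        return quadrature(self._fn, self.breakpoints)

    def to_dict(self) -> dict:
        return {"kind": self.kind, **self.params}


def logistic_density(steepness: float = 20.0, midpoint: float = 0.5) -> ChromosomeDensity:
    """Logistic nucleoid profile ρ̂(x) = 1 / (1 + exp(steepness·(x − midpoint))).

    The defaults (steepness 20, midpoint 1/2) are the experimentally motivated
    main-text profile; the logistic is symmetric about its midpoint so the
    defaults carry mass 1/2 exactly.  Off-default parameters are rescaled to
    preserve ∫₀¹ ρ̂ = 1/2.
    """
    if not steepness > 0:
        raise ValueError(f"steepness must be > 0, got {steepness}")
    if not 0.0 < midpoint < 1.0:
        raise ValueError(f"midpoint must lie in (0, 1), got {midpoint}")

    def raw(x):
        return 1.0 / (1.0 + np.exp(steepness * (x - midpoint)))

    mass = quadrature(raw)
    scale = DENSITY_MASS / mass

    def fn(x):
        return scale * raw(x)

    return ChromosomeDensity(
        kind="logistic",
        params={"steepness": steepness, "midpoint": midpoint},
        _fn=fn,
    )


def step_density(delta_x: float) -> ChromosomeDensity:
    """Step nucleoid: uniform on [0, 1−Δx), zero in the DNA-free pole region.

    The height 1/(2(1−Δx)) enforces ∫₀¹ ρ̂ = 1/2.  At the discontinuity the
    left (chromosome-side) value is returned; integrals are computed piecewise
    so the measure-zero choice is irrelevant.
    """
    if not 0.0 < delta_x < 1.0:
        raise ValueError(f"delta_x must lie in (0, 1), got {delta_x}")
    edge = 1.0 - delta_x
    height = DENSITY_MASS / edge

    def fn(x):
        return np.where(x <= edge, height, 0.0)

    return ChromosomeDensity(
        kind="step",
        params={"delta_x": delta_x},
        _fn=fn,
        breakpoints=(edge,),
    )


def custom_density(x: Sequence[float], values: Sequence[float]) -> ChromosomeDensity:
    """Tabulated density, linearly interpolated and renormalized to mass 1/2.

    Warns if the renormalization correction exceeds 1%.
    """
    x = np.asarray(x, dtype=float)
    values = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.shape != values.shape or x.size < 2:
        raise ValueError("x and values must be matching 1-D arrays with at least 2 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if np.any(values < 0):
        raise ValueError("density values must be non-negative")

    def raw(q):
        return np.interp(q, x, values)

    mass = quadrature(raw, check=False)
    if mass <= 0:
        raise ValueError("tabulated density has zero mass")
    scale = DENSITY_MASS / mass
    if abs(scale - 1.0) > 0.01:
        warnings.warn(
            f"custom density renormalized by factor {scale:.4f} to reach mass 1/2",
            UserWarning,
            stacklevel=2,
        )

    def fn(q):
        return scale * np.interp(q, x, values)

    return ChromosomeDensity(
        kind="custom",
        params={"x": tuple(map(float, x)), "values": tuple(float(s * scale) for s in values)},
        _fn=fn,
        # interior knots are slope discontinuities: integrate piecewise
        breakpoints=tuple(float(q) for q in x if 0.0 < q < 1.0),
    )


def density_from_dict(spec: dict) -> ChromosomeDensity:
    """Rebuild a density from its :meth:`ChromosomeDensity.to_dict` form."""
    spec = dict(spec)
    kind = spec.pop("kind", "logistic")
    if kind == "logistic":
        return logistic_density(**spec)
    if kind == "step":
        return step_density(**spec)
    if kind == "custom":
        return custom_density(spec["x"], spec["values"])
    raise ValueError(f"unknown density kind {kind!r}")


@dataclass(frozen=True)
class VolumeProfile:
    """Available-volume fraction v(x) = scale · exp(−r_rel² ρ̂(x)).

    ``scale`` is 1 for a raw profile; :func:`normalize_profile` sets it to
    1/∫₀¹ exp(−r_rel² ρ̂) dx so that ∫₀¹ v̂ = 1.
    """

    density: ChromosomeDensity
    r_rel: float
    scale: float = 1.0

    def __call__(self, x):
        return self.scale * np.exp(-self.r_rel**2 * self.density(x))

    def integral(self) -> float:
        """∫₀¹ v(x) dx for the current (possibly scaled) profile."""
        return self.scale * self._base_integral()

    def _base_integral(self) -> float:
        rho = self.density
        k = self.r_rel**2
        return quadrature(lambda x: np.exp(-k * rho(x)), rho.breakpoints)

    @property
    def is_normalized(self) -> bool:
        return abs(self.integral() - 1.0) < 1e-9


def available_volume(density: ChromosomeDensity, r_rel: float) -> VolumeProfile:
    """Available-volume profile of a species with radius ratio r/r* = ``r_rel``."""
    if r_rel < 0:
        raise ValueError(f"r_rel must be >= 0, got {r_rel}")
    return VolumeProfile(density=density, r_rel=float(r_rel))


class IncompatibleProfilesError(ValueError):
    """Two profiles built on different chromosome densities cannot combine."""


def _check_same_density(*profiles: VolumeProfile) -> ChromosomeDensity:
    d0 = profiles[0].density
    for p in profiles[1:]:
        if p.density is not d0 and p.density != d0:
            raise IncompatibleProfilesError(
                "profiles are built on different chromosome densities"
            )
    return d0


def complex_volume(vE: VolumeProfile, vS: VolumeProfile) -> VolumeProfile:
    """Available-volume profile of the E·S complex: vc = vE·vS.

    Hopping into the mesh requires free volume for both partners, so the
    probabilities multiply, i.e. the squared radius ratios add:
    r_c² = r_E² + r_S².
    """
    density = _check_same_density(vE, vS)
    r_rel = float(np.hypot(vE.r_rel, vS.r_rel))
    return VolumeProfile(density=density, r_rel=r_rel, scale=vE.scale * vS.scale)


def normalize_profile(v: VolumeProfile) -> VolumeProfile:
    """Return v̂ = v / ∫₀¹ v dx (idempotent; scale recomputed from the raw profile)."""
    base = v._base_integral()
    if not np.isfinite(base) or base <= 0:
        raise ValueError("cannot normalize a non-positive profile")
    return VolumeProfile(density=v.density, r_rel=v.r_rel, scale=1.0 / base)


def r_star(Vp: float, Lp: float, kappa: float) -> float:
    """Exclusion length scale r* from (r*)² = Vp / (2 κ π Lp).

    Vp is the volume confining the DNA polymer, Lp the total DNA contour
    length, κ an empirical correction factor; Lp/Vp is DNA length per volume.
    """
    for name, val in (("Vp", Vp), ("Lp", Lp), ("kappa", kappa)):
        if not val > 0:
            raise ValueError(f"{name} must be > 0, got {val}")
    return float(np.sqrt(Vp / (2.0 * kappa * np.pi * Lp)))


def profile_table(v: VolumeProfile, n: int = 401) -> "np.ndarray":
    """Two-column array (x, v(x)) for CSV export."""
    x = np.linspace(0.0, 1.0, n)
    return np.column_stack([x, v(x)])
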