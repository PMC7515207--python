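"""Preset circuit models and closed-form steady states.

Covers the core applications of the BCF framework:

* transcription/translation (gene + RNAP, Case II; mRNA + ribosome, Case I),
* polysome translation (an mRNA loading Nr ribosomes),
* a dimerizing transcriptional repressor,
* the activator–repressor clock, with its quasi-steady-state (QSSA) Hill
  reduction, and oscillation detection.

All rates are dimensionless (time in units of the dilution rate, μ = 1,
unless a parameter explicitly lumps dilution into a decay constant γ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .bcf import bcf_case1, bcf_fixed
from .geometry import (
    ChromosomeDensity,
    available_volume,
    logistic_density,
    normalize_profile,
)
from .network import (
    BindingReaction,
    CircuitModel,
    Fixed,
    Production,
    SpeciesSpec,
)
from .pde import IntegrationFailure
from .reduced import find_steady_state

logger = logging.getLogger(__name__)

__all__ = [
    "TxTlParams",
    "PolysomeParams",
    "RepressorParams",
    "ClockParams",
    "ResolvedClock",
    "txtl_model",
    "mrna_total_ss",
    "protein_ss",
    "polysome_protein_ss",
    "polysome_reduced_ss",
    "repression_ss",
    "simulate_repressor",
    "repressor_reduced_ss",
    "clock_qssa_params",
    "simulate_clock",
    "detect_oscillations",
    "OscillationReport",
    "PAPER_ESTIMATES",
]

#: Literature-derived worked-example radius ratios: RNAP r_s/r* ≈ 0.3
#: (r_s = 6.5 nm), mRNA r_m/r* ≈ 0.88 (20 nm), ribosome r_R/r* ≈ 0.44
#: (10 nm), and Nr = 10 ribosomes per 700-nt polysome.
PAPER_ESTIMATES = {"rs_rel": 0.3, "rm_rel": 0.88, "rR_rel": 0.44, "Nr": 10}


# ---------------------------------------------------------------------------
# transcription / translation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TxTlParams:
    """Transcription–translation chain: gene D + RNAP S → mRNA m; m + ribosome R → protein P.

    Rates are chosen so binding is fast (η ≪ 1) relative to dilution.
    ``Ks``/``KR`` are the textbook dissociation constants d/a; the exact
    steady-state Hill forms of the reduced model use the lumped constants
    (d + κ + γ + 1)/a, to which Ks and KR are the fast-unbinding limits.
    """

    a_s: float = 10.0
    d_s: float = 50.0
    kappa_s: float = 10.0
    a_m: float = 10.0
    d_m: float = 50.0
    kappa_m: float = 10.0
    alpha_s: float = 1.0
    alpha_r: float = 5.0
    gamma: float = 1.0        # mRNA degradation
    D_T: float = 0.1          # total gene, space-averaged
    x_star: float = 1.0       # gene location
    delta: float = 0.02
    rs_rel: float = 0.3
    rm_rel: float = 0.88
    rR_rel: float = 0.44
    epsilon: float = 1e-3

    @property
    def Ks(self) -> float:
        return self.d_s / self.a_s

    @property
    def KR(self) -> float:
        return self.d_m / self.a_m

    @property
    def Ks_eff(self) -> float:
        """Exact RNAP–gene lumped dissociation constant (ds + κs + 1)/as."""
        return (self.d_s + self.kappa_s + 1.0) / self.a_s

    @property
    def KR_eff(self) -> float:
        """Exact ribosome–mRNA lumped dissociation constant (dm + κm + γ + 1)/am."""
        return (self.d_m + self.kappa_m + self.gamma + 1.0) / self.a_m


def txtl_model(p: TxTlParams, density: ChromosomeDensity | None = None) -> CircuitModel:
    """Full transcription/translation circuit as a generic binding network.

    The gene D is fixed and conserved (copy number maintained through
    growth); RNAP and ribosomes are produced at constant rates and diluted.
    """
    if density is None:
        density = logistic_density()
    species = [
        SpeciesSpec("D", r_rel=0.0, mobility=Fixed(p.x_star, p.delta),
                    conserved=True, initial_total=p.D_T),
        SpeciesSpec("S", r_rel=p.rs_rel),
        SpeciesSpec("m", r_rel=p.rm_rel, gamma=p.gamma),
        SpeciesSpec("R", r_rel=p.rR_rel),
        SpeciesSpec("P", r_rel=0.0),
    ]
    reactions = [
        BindingReaction("D", "S", a=p.a_s, d=p.d_s, kappa=p.kappa_s, product="m"),
        BindingReaction("m", "R", a=p.a_m, d=p.d_m, kappa=p.kappa_m, product="P"),
    ]
    productions = {
        "S": Production(alpha_bar=p.alpha_s),
        "R": Production(alpha_bar=p.alpha_r),
    }
    return CircuitModel(
        species=species,
        reactions=reactions,
        productions=productions,
        epsilon=p.epsilon,
        density=density,
        name="txtl",
    )


def mrna_total_ss(p: TxTlParams, S_bar: float, thetaS: float) -> float:
    """Steady-state total mRNA m̄T = m̄ + c̄m as a Hill function of RNAP occupancy.

        m̄T = (κs / (γ+1)) · D̄T · (S̄ θS / K) / (1 + S̄ θS / K)

    with K the lumped gene–RNAP dissociation constant.  m̄T is independent
    of the translation BCF θR; it is linear in θS at low occupancy and
    saturates to κs D̄T/(γ+1) at high RNAP.
    """
    occ = S_bar * thetaS / p.Ks_eff
    return p.kappa_s / (p.gamma + 1.0) * p.D_T * occ / (1.0 + occ)


def protein_ss(p: TxTlParams, m_T: float, R_bar: float, thetaR: float) -> float:
    """Steady-state protein P̄ = κm c̄m with c̄m Hill in ribosome occupancy R̄θR/K."""
    occ = R_bar * thetaR / p.KR_eff
    return p.kappa_m * m_T * occ / (1.0 + occ)


# ---------------------------------------------------------------------------
# polysome translation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolysomeParams:
    """Polysome translation: m + (Nr−1) R ⇌ c_l (loading); c_l + R ⇌ c_t → P (release).

    Defaults satisfy the fast-unbinding regime βl = βt = 1e−3 and low
    ribosome saturation of the release step (R̄/Kt ≪ 1) under which the
    closed-form protein expression holds.
    """

    Nr: int = 10
    a_l: float = 671.9       # dl / Kd^(Nr-1) with Kd ≈ 1.129
    d_l: float = 2000.0
    a_t: float = 20.0
    d_t: float = 1000.0
    kappa_t: float = 1000.0
    gamma: float = 1.0       # mRNA degradation

    def __post_init__(self):
        if self.Nr < 2:
            raise ValueError("the loading step requires Nr >= 2")

    @property
    def Kd(self) -> float:
        return (self.d_l / self.a_l) ** (1.0 / (self.Nr - 1))

    @property
    def Kt(self) -> float:
        return (self.d_t + self.kappa_t) / self.a_t

    @property
    def beta_l(self) -> float:
        return (self.gamma + 1.0) / self.d_l

    @property
    def beta_t(self) -> float:
        return (self.gamma + 1.0) / (self.kappa_t + self.d_t)


def polysome_protein_ss(
    p: PolysomeParams, m_T: float, R_bar: float, thetaL: float, thetaT: float
) -> float:
    """Closed-form steady-state protein for polysome translation:

        P̄ = κt m̄T (θt R̄ / Kt) · θl (R̄/Kd)^{Nr−1} / (1 + θl (R̄/Kd)^{Nr−1})

    valid for βl, βt, R̄/Kt ≪ 1.  At low loading saturation the ratio to the
    well-mixed value is θl·θt, the joint amplification of loading and release.
    """
    x = thetaL * (R_bar / p.Kd) ** (p.Nr - 1)
    return p.kappa_t * m_T * (thetaT * R_bar / p.Kt) * x / (1.0 + x)


def polysome_reduced_ss(
    p: PolysomeParams, m_T: float, R_bar: float, thetaL: float, thetaT: float
) -> float:
    """Steady-state protein from the full reduced polysome ODE (mass action,
    association rates multiplied by θl*/θt*), used as an internal consistency
    oracle for :func:`polysome_protein_ss`.

    State (c̄l, c̄t, P̄) with m̄ = m̄T − c̄l − c̄t and the free-ribosome pool R̄
    held constant (ribosomes in excess).
    """

    g1 = p.gamma + 1.0

    def rhs(t, y):
        cl, ct, P = y
        m = m_T - cl - ct
        load = p.a_l * thetaL * m * R_bar ** (p.Nr - 1) - p.d_l * cl
        rel = p.a_t * thetaT * cl * R_bar - (p.d_t + p.kappa_t) * ct
        return np.array([
            load - rel - g1 * cl,
            rel - g1 * ct,
            p.kappa_t * ct - P,
        ])

    y = find_steady_state(rhs, np.zeros(3), t_probe=50.0)
    return float(y[2])


# ---------------------------------------------------------------------------
# dimerizing transcriptional repressor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepressorParams:
    """Repressor Pr dimerizes (Case I) and the dimer blocks a fixed gene (Case II).

    Transcription + translation of Pr and of the output P are lumped into
    single production steps (rates α and κ); γr and γp are total decay rates.
    """

    alpha: float = 1.0
    a1: float = 100.0
    d1: float = 100.0
    a2: float = 100.0
    d2: float = 100.0
    kappa: float = 1.0
    gamma_r: float = 1.0
    gamma_p: float = 1.0
    x_star: float = 1.0
    r_rel: float = 1.0

    @property
    def K(self) -> float:
        """Effective repression constant K = sqrt(Kd1 · Kd2)."""
        return float(np.sqrt((self.d1 / self.a1) * (self.d2 / self.a2)))


def _repressor_thetas(p: RepressorParams, density: ChromosomeDensity) -> tuple[float, float]:
    vPr = available_volume(density, p.r_rel)
    v_dimer = available_volume(density, np.sqrt(2.0) * p.r_rel)
    theta1 = bcf_case1(vPr, vPr).value
    theta2 = bcf_fixed(v_dimer, p.x_star).value
    return theta1, theta2


def repression_ss(
    p: RepressorParams, Pr_bar: float, density: ChromosomeDensity | None = None
) -> tuple[float, float]:
    """Closed-form steady state of the repressed gene: (free-DNA fraction D̄, output P̄).

        D̄ = 1 / (1 + (P̄r/K)² θ*),   P̄ = κ D̄ / γp,
        θ* = θ1* θ2* = v̂_Pr(x*)²,

    so all spatial information enters through the square of the repressor's
    normalized available volume at the gene location: a big repressor
    ejected to the poles silences pole-localized genes more strongly than
    mid-cell genes.
    """
    if density is None:
        density = logistic_density()
    vhat = normalize_profile(available_volume(density, p.r_rel))
    theta = float(vhat(p.x_star)) ** 2
    D_bar = 1.0 / (1.0 + (Pr_bar / p.K) ** 2 * theta)
    return D_bar, p.kappa * D_bar / p.gamma_p


def _repressor_rhs(p: RepressorParams, theta1: float, theta2: float):
    def rhs(t, y):
        Pr, c1, c2, P = y
        D = 1.0 - c2
        bind2 = p.a2 * theta2 * c1 * D - p.d2 * c2
        return np.array([
            p.alpha - p.gamma_r * Pr,
            p.a1 * theta1 * Pr**2 - p.d1 * c1 - bind2,
            bind2,
            p.kappa * D - p.gamma_p * P,
        ])

    return rhs


def simulate_repressor(
    p: RepressorParams,
    density: ChromosomeDensity | None = None,
    theta="auto",
    t_end: float = 20.0,
    n_saves: int = 201,
):
    """Integrate the repressor reduced ODE (states P̄r, c̄1, c̄2, P̄; D̄ = 1 − c̄2)."""
    if density is None:
        density = logistic_density()
    if isinstance(theta, str) and theta == "auto":
        theta1, theta2 = _repressor_thetas(p, density)
    else:
        theta1 = theta2 = float(theta)
    rhs = _repressor_rhs(p, theta1, theta2)
    t_eval = np.linspace(0.0, t_end, n_saves)
    sol = solve_ivp(rhs, (0.0, t_end), np.zeros(4), method="BDF",
                    t_eval=t_eval, rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise IntegrationFailure(sol.message)
    return sol.t, {name: sol.y[k] for k, name in enumerate(["Pr", "c1", "c2", "P"])}


def repressor_reduced_ss(
    p: RepressorParams, density: ChromosomeDensity | None = None, theta="auto"
) -> dict[str, float]:
    """Steady state of the repressor reduced ODE via long-time integration + Newton."""
    if density is None:
        density = logistic_density()
    if isinstance(theta, str) and theta == "auto":
        theta1, theta2 = _repressor_thetas(p, density)
    else:
        theta1 = theta2 = float(theta)
    y = find_steady_state(_repressor_rhs(p, theta1, theta2), np.zeros(4), t_probe=100.0)
    out = dict(zip(["Pr", "c1", "c2", "P"], map(float, y)))
    out["D"] = 1.0 - out["c2"]
    return out


# ---------------------------------------------------------------------------
# activator–repressor clock
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClockParams:
    """Activator–repressor clock from elementary binding rates.

    The activator Pa dimerizes and activates its own gene Da and the
    repressor gene Dr; the repressor Pr dimerizes and represses Da.  The
    defaults put the well-mixed QSSA model (Hill coefficient 2) in its
    oscillatory regime — the activator decays much faster than the
    repressor (γa ≫ γr), the relaxation-oscillator condition.
    """

    # elementary association/dissociation: 1 Pa dimer., 2 Pr dimer.,
    # 3 Pa2+Da, 4 Pa2+Dr, 5 Pr2+Da
    a1: float = 50.0
    d1: float = 50.0
    a2: float = 50.0
    d2: float = 50.0
    a3: float = 50.0
    d3: float = 50.0
    a4: float = 50.0
    d4: float = 50.0
    a5: float = 50.0
    d5: float = 50.0
    kappa1: float = 0.04     # basal Da transcription -> alpha0A
    kappa2: float = 0.004    # basal Dr transcription -> alpha0R
    kappa3: float = 25.0     # activated Da transcription -> alphaA
    kappa4: float = 1.5      # activated Dr transcription -> alphaR
    gamma_a: float = 1.0
    gamma_r: float = 0.1
    Da_T: float = 1.0
    Dr_T: float = 1.0
    ra_rel: float = 1e-3
    rr_rel: float = 1e-3
    xa_star: float = 1.0
    xr_star: float = 1.0


@dataclass(frozen=True)
class ClockThetas:
    theta1: float  # Pa dimerization, Case I
    theta2: float  # Pr dimerization, Case I
    theta3: float  # Pa2 + Da, Case III, at xa*
    theta4: float  # Pa2 + Dr, Case III, at xr*
    theta5: float  # Pr2 + Da, Case III, at xa*


@dataclass(frozen=True)
class ResolvedClock:
    """QSSA (Hill) clock parameters with BCFs folded into the Kd's."""

    alpha0A: float
    alphaA: float
    alpha0R: float
    alphaR: float
    Kd1: float
    Kd2: float
    Kd3: float
    gamma_a: float
    gamma_r: float
    thetaA1: float
    thetaR: float
    thetaA2: float


def _clock_thetas(p: ClockParams, density: ChromosomeDensity) -> ClockThetas:
    vPa = available_volume(density, p.ra_rel)
    vPr = available_volume(density, p.rr_rel)
    vPa2 = available_volume(density, np.sqrt(2.0) * p.ra_rel)
    vPr2 = available_volume(density, np.sqrt(2.0) * p.rr_rel)
    return ClockThetas(
        theta1=bcf_case1(vPa, vPa).value,
        theta2=bcf_case1(vPr, vPr).value,
        theta3=bcf_fixed(vPa2, p.xa_star).value,
        theta4=bcf_fixed(vPa2, p.xr_star).value,
        theta5=bcf_fixed(vPr2, p.xa_star).value,
    )


def clock_qssa_params(
    p: ClockParams, density: ChromosomeDensity | None = None, well_mixed: bool = False
) -> ResolvedClock:
    """Resolve the Hill-form clock parameters, folding the BCFs into the Kd's:

        Kd,1 = sqrt(d1 d3 / (θA1 a1 a3)),  θA1 = θ1 θ3 = v̂_Pa(xa*),
        Kd,2 = sqrt(d2 d5 / (θR  a2 a5)),  θR  = θ2 θ5 = v̂_Pr(xa*),
        Kd,3 = sqrt(d1 d4 / (θA2 a1 a4)),  θA2 = θ1 θ4 = v̂_Pa(xr*).
    """
    if density is None:
        density = logistic_density()
    if well_mixed:
        thA1 = thR = thA2 = 1.0
    else:
        th = _clock_thetas(p, density)
        thA1 = th.theta1 * th.theta3
        thR = th.theta2 * th.theta5
        thA2 = th.theta1 * th.theta4
    return ResolvedClock(
        alpha0A=p.kappa1 * p.Da_T,
        alphaA=p.kappa3,
        alpha0R=p.kappa2 * p.Dr_T,
        alphaR=p.kappa4 * p.Dr_T,
        Kd1=float(np.sqrt(p.d1 * p.d3 / (thA1 * p.a1 * p.a3))),
        Kd2=float(np.sqrt(p.d2 * p.d5 / (thR * p.a2 * p.a5))),
        Kd3=float(np.sqrt(p.d1 * p.d4 / (thA2 * p.a1 * p.a4))),
        gamma_a=p.gamma_a,
        gamma_r=p.gamma_r,
        thetaA1=thA1,
        thetaR=thR,
        thetaA2=thA2,
    )


def _qssa_rhs(q: ResolvedClock):
    def rhs(t, y):
        Pa, Pr = y
        u = (Pa / q.Kd1) ** 2
        w = (Pr / q.Kd2) ** 2
        s = (Pa / q.Kd3) ** 2
        return np.array([
            (q.alpha0A + q.alphaA * u) / (1.0 + u + w) - q.gamma_a * Pa,
            (q.alpha0R + q.alphaR * s) / (1.0 + s) - q.gamma_r * Pr,
        ])

    return rhs


def _full_reduced_rhs(p: ClockParams, th: ClockThetas):
    def rhs(t, y):
        Pa, Pr, Pa2, Pr2, ca1, ca2, cr = y
        Da = p.Da_T - ca1 - cr
        Dr = p.Dr_T - ca2
        b3 = p.a3 * th.theta3 * Pa2 * Da - p.d3 * ca1
        b4 = p.a4 * th.theta4 * Pa2 * Dr - p.d4 * ca2
        b5 = p.a5 * th.theta5 * Pr2 * Da - p.d5 * cr
        return np.array([
            p.kappa1 * Da + p.kappa3 * ca1 - p.gamma_a * Pa,
            p.kappa2 * Dr + p.kappa4 * ca2 - p.gamma_r * Pr,
            p.a1 * th.theta1 * Pa**2 - p.d1 * Pa2 - b3 - b4,
            p.a2 * th.theta2 * Pr**2 - p.d2 * Pr2 - b5,
            b3,
            b4,
            b5,
        ])

    return rhs


def simulate_clock(
    p: ClockParams,
    mode: str = "qssa",
    t_end: float = 400.0,
    density: ChromosomeDensity | None = None,
    n_saves: int = 2001,
    y0=None,
):
    """Integrate the clock in one of three variants.

    ``mode``: "reduced" (full reduced binding model), "qssa" (the two-state
    Hill reduction, valid when unbinding is much faster than protein decay),
    or "well-mixed" (all θ* forced to 1).  Returns (times, averages dict);
    the reported states always include Pa and Pr.
    """
    if density is None:
        density = logistic_density()
    if mode not in {"reduced", "qssa", "well-mixed"}:
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "qssa":
        sep = min(p.d1, p.d2, p.d3, p.d4, p.d5) / max(p.gamma_a, p.gamma_r)
        if sep < 50.0:
            logger.info(
                "QSSA separation check failed (min d_i / max gamma = %.1f < 50); "
                "integrating the full reduced model instead", sep
            )
            mode = "reduced"

    if mode == "qssa":
        q = clock_qssa_params(p, density)
        rhs = _qssa_rhs(q)
        names = ["Pa", "Pr"]
        start = np.zeros(2) if y0 is None else np.asarray(y0, dtype=float)
    else:
        if mode == "well-mixed":
            th = ClockThetas(1.0, 1.0, 1.0, 1.0, 1.0)
        else:
            th = _clock_thetas(p, density)
        rhs = _full_reduced_rhs(p, th)
        names = ["Pa", "Pr", "Pa2", "Pr2", "ca1", "ca2", "cr"]
        start = np.zeros(7) if y0 is None else np.asarray(y0, dtype=float)

    t_eval = np.linspace(0.0, t_end, n_saves)
    sol = solve_ivp(rhs, (0.0, t_end), start, method="BDF",
                    t_eval=t_eval, rtol=1e-8, atol=1e-11)
    if not sol.success:
        raise IntegrationFailure(f"clock integration failed: {sol.message}")
    return sol.t, {name: sol.y[k] for k, name in enumerate(names)}


# ---------------------------------------------------------------------------
# oscillation detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OscillationReport:
    oscillating: bool
    amplitude: float
    period: float | None
    n_peaks: int


class InsufficientDataError(ValueError):
    """Trajectory too short to assess oscillation."""


def detect_oscillations(times, signal, min_points: int = 50) -> OscillationReport:
    """Decide whether a trajectory shows sustained oscillations.

    The first half of the record (the transient) is discarded.  The signal
    oscillates if, over the second half, the peak-to-trough amplitude
    exceeds 1% of the signal mean, at least 3 maxima occur, and the
    coefficient of variation of inter-peak intervals is below 0.2 (regular
    spacing).  The period is the mean inter-peak interval.
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if times.size != signal.size or times.size < min_points:
        raise InsufficientDataError(
            f"need at least {min_points} samples, got {times.size}"
        )
    half = times.size // 2
    t, y = times[half:], signal[half:]
    mean = float(np.mean(y))
    amplitude = float(y.max() - y.min())
    if mean <= 0 or amplitude < 0.01 * mean:
        return OscillationReport(False, amplitude, None, 0)
    peaks, _ = find_peaks(y, prominence=0.25 * amplitude)
    if peaks.size < 3:
        return OscillationReport(False, amplitude, None, int(peaks.size))
    intervals = np.diff(t[peaks])
    cv = float(np.std(intervals) / np.mean(intervals))
    if cv >= 0.2:
        return OscillationReport(False, amplitude, None, int(peaks.size))
    return OscillationReport(True, amplitude, float(np.mean(intervals)), int(peaks.size))
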