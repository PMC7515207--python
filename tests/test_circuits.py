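"""Preset circuits: transcription/translation, polysome, repressor, clock."""

import dataclasses

import numpy as np
import pytest

import spatialcircuits as sc
from spatialcircuits.circuits import (
    ClockParams,
    InsufficientDataError,
    PolysomeParams,
    RepressorParams,
    TxTlParams,
    clock_qssa_params,
    detect_oscillations,
    mrna_total_ss,
    polysome_protein_ss,
    polysome_reduced_ss,
    protein_ss,
    repression_ss,
    repressor_reduced_ss,
    simulate_clock,
)


class TestTranscription:
    def test_well_mixed_baseline_and_saturation(self):
        p = TxTlParams()
        base = mrna_total_ss(p, S_bar=1.0, thetaS=1.0)
        assert 0 < base < p.kappa_s * p.D_T / (p.gamma + 1.0)
        # saturation: independent of theta at very high RNAP
        hi1 = mrna_total_ss(p, S_bar=1e7, thetaS=1.0)
        hi2 = mrna_total_ss(p, S_bar=1e7, thetaS=1.5)
        limit = p.kappa_s * p.D_T / (p.gamma + 1.0)
        assert hi1 == pytest.approx(limit, rel=1e-5)
        assert hi2 == pytest.approx(limit, rel=1e-5)

    def test_low_occupancy_linear_in_theta(self):
        p = TxTlParams()
        S = 1e-4
        r = mrna_total_ss(p, S, thetaS=1.2) / mrna_total_ss(p, S, thetaS=1.0)
        assert r == pytest.approx(1.2, rel=1e-3)

    def test_protein_increases_with_translation_bcf(self, logistic):
        p = TxTlParams()
        thetaR = sc.bcf_case1(
            sc.available_volume(logistic, p.rm_rel), sc.available_volume(logistic, p.rR_rel)
        ).value
        assert thetaR > 1.0
        assert protein_ss(p, 0.05, 1.0, thetaR) > protein_ss(p, 0.05, 1.0, 1.0)


class TestPolysome:
    def test_closed_form_matches_reduced_ode(self, logistic):
        loading, release = sc.bcf_polysome(0.88, 0.44, 10, logistic)
        p = PolysomeParams()
        closed = polysome_protein_ss(p, 0.1, 1.0, loading.value, release.value)
        ode = polysome_reduced_ss(p, 0.1, 1.0, loading.value, release.value)
        assert closed == pytest.approx(ode, rel=0.01)

    def test_low_saturation_gain_is_theta_product(self, logistic):
        loading, release = sc.bcf_polysome(0.88, 0.44, 10, logistic)
        p = PolysomeParams(a_l=2.0)  # large Kd: deep in the unsaturated regime
        gain = polysome_protein_ss(p, 0.1, 1.0, loading.value, release.value) / \
            polysome_protein_ss(p, 0.1, 1.0, 1.0, 1.0)
        assert gain == pytest.approx(loading.value * release.value, rel=5e-3)

    def test_well_mixed_baseline(self):
        p = PolysomeParams()
        assert polysome_protein_ss(p, 0.1, 1.0, 1.0, 1.0) > 0

    def test_nr_lower_bound(self):
        with pytest.raises(ValueError):
            PolysomeParams(Nr=1)


class TestRepressor:
    def test_no_repressor_full_expression(self):
        p = RepressorParams()
        D, P = repression_ss(p, 0.0)
        assert D == pytest.approx(1.0)
        assert P == pytest.approx(p.kappa / p.gamma_p)

    def test_point_repressor_is_well_mixed(self, logistic):
        p = RepressorParams(r_rel=0.0)
        D, _ = repression_ss(p, 1.0, logistic)
        assert D == pytest.approx(1.0 / (1.0 + (1.0 / p.K) ** 2), rel=1e-10)

    def test_location_ordering_for_large_repressor(self, logistic):
        # big repressor: stronger repression (smaller D) at the pole, weaker mid-cell
        Pr = 1.0
        D_pole, _ = repression_ss(RepressorParams(r_rel=1.5, x_star=1.0), Pr, logistic)
        D_wm, _ = repression_ss(RepressorParams(r_rel=0.0, x_star=1.0), Pr, logistic)
        D_mid, _ = repression_ss(RepressorParams(r_rel=1.5, x_star=0.0), Pr, logistic)
        assert D_pole < D_wm < D_mid

    def test_reduced_ode_matches_closed_form(self, logistic):
        p = RepressorParams()
        ss = repressor_reduced_ss(p, logistic)
        D, P = repression_ss(p, p.alpha / p.gamma_r, logistic)
        assert ss["D"] == pytest.approx(D, rel=1e-8)
        assert ss["P"] == pytest.approx(P, rel=1e-8)


class TestClock:
    def test_qssa_parameters_reduce_to_well_mixed_for_point_proteins(self, logistic):
        p = ClockParams(ra_rel=0.0, rr_rel=0.0)
        q = clock_qssa_params(p, logistic)
        q_wm = clock_qssa_params(p, logistic, well_mixed=True)
        for attr in ("Kd1", "Kd2", "Kd3"):
            assert getattr(q, attr) == pytest.approx(getattr(q_wm, attr), rel=1e-12)

    def test_thetas_increase_with_activator_size_at_pole(self, logistic):
        vals = [
            clock_qssa_params(ClockParams(ra_rel=r), logistic).thetaA1
            for r in [0.1, 0.5, 1.0]
        ]
        assert vals[0] > 1.0 - 1e-9
        assert np.all(np.diff(vals) > 0)

    def test_theta_identities_match_profile_evaluation(self, logistic):
        # thetaA1 = theta1*theta3 must equal the squared normalized activator
        # profile at the gene location (and similarly for the others)
        p = ClockParams(ra_rel=0.8, rr_rel=0.3, xa_star=1.0, xr_star=0.6)
        q = clock_qssa_params(p, logistic)
        vhat_a = sc.normalize_profile(sc.available_volume(logistic, 0.8))
        vhat_r = sc.normalize_profile(sc.available_volume(logistic, 0.3))
        assert q.thetaA1 == pytest.approx(float(vhat_a(1.0)) ** 2, rel=1e-9)
        assert q.thetaA2 == pytest.approx(float(vhat_a(0.6)) ** 2, rel=1e-9)
        assert q.thetaR == pytest.approx(float(vhat_r(1.0)) ** 2, rel=1e-9)

    def test_qssa_matches_full_reduced_when_binding_fast(self):
        p = ClockParams()
        fast = dataclasses.replace(
            p, **{k: getattr(p, k) * 100 for k in ["a1", "a2", "a3", "a4", "a5",
                                                    "d1", "d2", "d3", "d4", "d5"]}
        )
        t, fr = simulate_clock(fast, mode="reduced", t_end=30.0, n_saves=601)
        _, qs = simulate_clock(fast, mode="qssa", t_end=30.0, n_saves=601)
        err = np.abs(fr["Pa"] - qs["Pa"]).max() / np.abs(qs["Pa"]).max()
        assert err < 0.02

    def test_qssa_falls_back_when_separation_poor(self, caplog):
        import logging

        slow = ClockParams(d1=1.0, d2=1.0, d3=1.0, d4=1.0, d5=1.0)
        with caplog.at_level(logging.INFO, logger="spatialcircuits.circuits"):
            _, traj = simulate_clock(slow, mode="qssa", t_end=5.0, n_saves=101)
        assert "separation check failed" in caplog.text
        assert "ca1" in traj  # full reduced states present


class TestOscillationDetection:
    def test_constant_not_oscillating(self):
        t = np.linspace(0, 100, 500)
        rep = detect_oscillations(t, np.full_like(t, 2.0))
        assert not rep.oscillating

    def test_sinusoid_recovers_period(self):
        t = np.linspace(0, 100, 2000)
        y = 1.0 + 0.1 * np.sin(2 * np.pi * t / 10.0)  # 10% of mean, 5 cycles/half-window
        rep = detect_oscillations(t, y)
        assert rep.oscillating
        assert rep.period == pytest.approx(10.0, rel=0.05)

    def test_damped_oscillation_rejected(self):
        t = np.linspace(0, 100, 2000)
        y = 1.0 + 0.5 * np.exp(-0.2 * t) * np.sin(2 * np.pi * t / 5.0)
        rep = detect_oscillations(t, y)
        assert not rep.oscillating

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            detect_oscillations(np.arange(10.0), np.arange(10.0))
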