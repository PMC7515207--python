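"""Binding correction factors: closed forms, limits, and the field-based estimator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import spatialcircuits as sc
from spatialcircuits.bcf import UndefinedBCFError
from spatialcircuits.geometry import IncompatibleProfilesError


def riemann_case1(density, rE, rS, n=100_000):
    """Independent brute-force Riemann-sum oracle for the Case I integral."""
    x = (np.arange(n) + 0.5) / n
    rho = density(x)
    num = np.mean(np.exp(-(rE**2 + rS**2) * rho))
    return num / (np.mean(np.exp(-rE**2 * rho)) * np.mean(np.exp(-rS**2 * rho)))


class TestCase1:
    def test_zero_radius_unity(self, logistic):
        for rE, rS in [(0.0, 0.7), (0.7, 0.0), (0.0, 0.0)]:
            res = sc.bcf_case1(
                sc.available_volume(logistic, rE), sc.available_volume(logistic, rS)
            )
            assert res.value == pytest.approx(1.0, abs=1e-12)

    def test_against_riemann_oracle(self, logistic):
        res = sc.bcf_case1(
            sc.available_volume(logistic, 0.88), sc.available_volume(logistic, 0.44)
        )
        assert res.value == pytest.approx(riemann_case1(logistic, 0.88, 0.44), abs=1e-6)

    @given(st.floats(0.05, 2.0), st.floats(0.05, 2.0))
    def test_at_least_unity_comonotone(self, rE, rS):
        d = sc.logistic_density()
        res = sc.bcf_case1(sc.available_volume(d, rE), sc.available_volume(d, rS))
        assert res.value >= 1.0 - 1e-12

    def test_monotone_in_radius(self, logistic):
        values = [
            sc.bcf_case1(
                sc.available_volume(logistic, r), sc.available_volume(logistic, r)
            ).value
            for r in [0.2, 0.5, 1.0, 2.0]
        ]
        assert np.all(np.diff(values) > 0)

    def test_step_density_upper_bound(self):
        # both radii -> infinity: co-localization in the DNA-free pole, theta -> 1/delta_x
        d = sc.step_density(0.25)
        res = sc.bcf_case1(sc.available_volume(d, 50.0), sc.available_volume(d, 50.0))
        assert res.value == pytest.approx(4.0, rel=0.01)

    def test_mismatched_densities_rejected(self, logistic):
        with pytest.raises(IncompatibleProfilesError):
            sc.bcf_case1(
                sc.available_volume(logistic, 0.1),
                sc.available_volume(sc.step_density(0.3), 0.1),
            )


class TestFixedSpecies:
    def test_zero_radius_unity_anywhere(self, logistic):
        v = sc.available_volume(logistic, 0.0)
        for xs in [0.0, 0.3, 1.0]:
            assert sc.bcf_fixed(v, xs).value == pytest.approx(1.0, abs=1e-12)

    def test_rnap_pole_and_midcell(self, logistic):
        # RNAP-sized species (r/r* = 0.3): enhancement at the pole, reduction mid-cell
        v = sc.available_volume(logistic, 0.3)
        pole = sc.bcf_fixed(v, 1.0).value
        mid = sc.bcf_fixed(v, 0.0).value
        assert pole == pytest.approx(1.06, abs=0.02)
        assert mid == pytest.approx(0.94, abs=0.02)

    @given(st.floats(0.0, 3.0))
    def test_pole_above_one_above_midcell(self, r_rel):
        d = sc.logistic_density()
        v = sc.available_volume(d, r_rel)
        assert sc.bcf_fixed(v, 1.0).value >= 1.0 - 1e-12 >= sc.bcf_fixed(v, 0.0).value - 2e-12

    def test_step_density_limits(self):
        d = sc.step_density(0.25)
        v = sc.available_volume(d, 50.0)
        assert sc.bcf_fixed(v, 1.0).value == pytest.approx(4.0, rel=0.01)
        assert sc.bcf_fixed(v, 0.0).value == pytest.approx(0.0, abs=0.04)

    def test_delta_smeared_converges_to_pointwise(self, logistic):
        v = sc.available_volume(logistic, 0.5)
        point = sc.bcf_fixed(v, 0.8).value
        smeared = [sc.bcf_fixed(v, 0.8, delta=dl).value for dl in [0.2, 0.05, 0.01]]
        errs = np.abs(np.array(smeared) - point)
        assert np.all(np.diff(errs) < 0) and errs[-1] < 1e-4

    def test_x_star_out_of_range(self, logistic):
        with pytest.raises(ValueError):
            sc.bcf_fixed(sc.available_volume(logistic, 0.1), 1.5)


class TestPolysome:
    def test_paper_estimates(self, logistic):
        loading, release = sc.bcf_polysome(0.88, 0.44, 10, logistic)
        assert loading.value == pytest.approx(1.56, abs=0.005)
        assert release.value == pytest.approx(1.07, abs=0.005)

    def test_single_ribosome_collapse(self, logistic):
        loading, release = sc.bcf_polysome(0.88, 0.44, 1, logistic)
        assert loading.value == pytest.approx(1.0, abs=1e-12)
        case1 = sc.bcf_case1(
            sc.available_volume(logistic, 0.88), sc.available_volume(logistic, 0.44)
        )
        assert release.value == pytest.approx(case1.value, rel=1e-12)

    def test_two_ribosome_loading_is_case1(self, logistic):
        loading, _ = sc.bcf_polysome(0.88, 0.44, 2, logistic)
        case1 = sc.bcf_case1(
            sc.available_volume(logistic, 0.88), sc.available_volume(logistic, 0.44)
        )
        assert loading.value == pytest.approx(case1.value, rel=1e-12)

    def test_point_radii_give_unity(self, logistic):
        loading, release = sc.bcf_polysome(0.0, 0.0, 10, logistic)
        assert loading.value == pytest.approx(1.0, abs=1e-12)
        assert release.value == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("nr", [0, -1])
    def test_invalid_nr(self, logistic, nr):
        with pytest.raises(ValueError):
            sc.bcf_polysome(0.88, 0.44, nr, logistic)


class TestFromFields:
    def test_constant_partner_gives_unity(self):
        rng = np.random.default_rng(7)
        E = rng.uniform(0.1, 2.0, 200)
        S = np.full(200, 0.8)
        assert sc.bcf_from_fields(E, S).value == pytest.approx(1.0, rel=1e-12)
        assert sc.bcf_from_fields(S, E).value == pytest.approx(1.0, rel=1e-12)

    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    def test_scale_invariance(self, cE, cS):
        rng = np.random.default_rng(3)
        E = rng.uniform(0.1, 2.0, 100)
        S = rng.uniform(0.1, 2.0, 100)
        base = sc.bcf_from_fields(E, S).value
        assert sc.bcf_from_fields(cE * E, cS * S).value == pytest.approx(base, rel=1e-10)

    def test_equilibrium_profiles_recover_case1(self, logistic):
        # fields shaped like their normalized available volumes (the fast-diffusion
        # quasi-equilibrium) must reproduce the Case I closed form
        n = 2000
        x = (np.arange(n) + 0.5) / n
        vhatE = sc.normalize_profile(sc.available_volume(logistic, 0.88))
        vhatS = sc.normalize_profile(sc.available_volume(logistic, 0.44))
        res = sc.bcf_from_fields(3.0 * vhatE(x), 0.5 * vhatS(x))
        expected = sc.bcf_case1(
            sc.available_volume(logistic, 0.88), sc.available_volume(logistic, 0.44)
        )
        assert res.value == pytest.approx(expected.value, rel=1e-5)

    def test_zero_mass_rejected(self):
        with pytest.raises(UndefinedBCFError):
            sc.bcf_from_fields(np.zeros(50), np.ones(50))
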