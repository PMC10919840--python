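"""Two-state crossbridge energetics: rates, forces, energy and efficiency."""

import numpy as np
import pytest

import myothermo as mt
from myothermo.huxley import _phi


class TestRateConstants:
    def test_direct_arithmetic_example(self, constants):
        # g1 = 2*(w/e)*b/(h*g); f1 = g*g1; g2 = 2*vmax/h
        f1, g1, g2 = mt.rate_constants(2.0, 2000.0, 3000.0, constants)
        assert (f1, g1, g2) == pytest.approx((300.0, 150.0, 600.0))

    def test_g2_from_control_vmax_matches_tabulated(self, constants):
        """Vmax = 3.8 Lo/s at a 1 µm half-sarcomere gives g2 within 2%
        of the tabulated 753 s⁻¹."""
        vmax_nm = constants.lo_per_s_to_nm_per_s(3.8)
        _, _, g2 = mt.rate_constants(1.5, 2000.0, vmax_nm, constants)
        assert g2 == pytest.approx(760.0)
        assert abs(g2 - 753.0) / 753.0 < 0.02

    @pytest.mark.parametrize("g", [0.5, 1.0, 2.0, 4.0])
    def test_f1_proportional_to_b_independent_of_curvature(self, g, constants):
        """f1 = 2(w/e)/h · b = 0.15·b for any curvature (algebraic)."""
        b = 2345.0
        f1, _, _ = mt.rate_constants(g, b, 3000.0, constants)
        assert f1 == pytest.approx(0.15 * b, rel=1e-12)

    def test_nonpositive_inputs_rejected(self, constants):
        with pytest.raises(mt.InvalidInputError):
            mt.rate_constants(-1.0, 2000.0, 3000.0, constants)


class TestUnitaryForce:
    @pytest.mark.parametrize("f1,g1,expected", [
        (314.0, 199.0, 1.6),   # control
        (306.0, 358.0, 1.2),   # 180 min anoxia
    ])
    def test_tabulated_cohort_means(self, f1, g1, expected, constants):
        assert mt.unitary_force(f1, g1, constants) == pytest.approx(
            expected, abs=0.05)

    def test_limit_duty_ratio_one(self, constants):
        """g1 → 0 at fixed f1 drives po to the ceiling w/l = 2.623 pN."""
        po = mt.unitary_force(314.0, 1e-12, constants)
        assert po == pytest.approx(constants.w_over_l_pN, rel=1e-9)
        assert constants.w_over_l_pN == pytest.approx(2.623, abs=1e-3)


class TestCatalyticConstant:
    def test_symmetric_rates(self, constants):
        # f1 = g1 = 100: kcat = (10/57.2)*50
        assert mt.catalytic_constant(100.0, 100.0, constants) == pytest.approx(
            (10.0 / 57.2) * 50.0, rel=1e-12)

    def test_control_means(self, constants):
        # direct arithmetic on the t=0 cohort means
        f1, g1 = 314.0, 199.0
        expected = (10.0 / (2 * 28.6)) * f1 * g1 / (f1 + g1)
        assert mt.catalytic_constant(f1, g1, constants) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(21.30, abs=0.01)

    def test_homogeneous_of_degree_one(self, constants):
        k1 = mt.catalytic_constant(314.0, 199.0, constants)
        k3 = mt.catalytic_constant(3 * 314.0, 3 * 199.0, constants)
        assert k3 == pytest.approx(3 * k1, rel=1e-12)


class TestEnergyRate:
    def test_isometric_closed_form(self, row0_rates, constants):
        f1, g1, _ = row0_rates
        n = 3.2e10
        expected = n * constants.e * (constants.h / (2 * constants.l)) \
            * f1 * g1 / (f1 + g1)
        assert mt.energy_rate(0.0, f1, g1, n, constants) == pytest.approx(
            expected, rel=1e-12)

    def test_high_velocity_plateau(self, row0_rates, constants):
        f1, g1, _ = row0_rates
        phi = _phi(f1, g1, constants)
        plateau = constants.e * (constants.h / (2 * constants.l)) * f1
        e_inf = mt.energy_rate(1e6 * phi, f1, g1, 1.0, constants)
        assert abs(e_inf / plateau - 1) < 1e-4

    def test_bracket_value_at_phi(self, row0_rates, constants):
        """At V = Φ the velocity factor is (1 − e⁻¹)."""
        f1, g1, _ = row0_rates
        phi = _phi(f1, g1, constants)
        bracket = g1 + f1 * (1 - np.exp(-1))
        assert bracket == pytest.approx(397.5, abs=0.05)
        e = mt.energy_rate(phi, f1, g1, 1.0, constants)
        pref = constants.e * (constants.h / (2 * constants.l)) * f1 / (f1 + g1)
        assert e == pytest.approx(pref * bracket, rel=1e-12)

    def test_strictly_increasing_in_velocity(self, row0_rates, constants):
        f1, g1, _ = row0_rates
        v = np.linspace(0, 10 * _phi(f1, g1, constants), 500)
        e = mt.energy_rate(v, f1, g1, 1.0, constants)
        assert np.all(np.diff(e) > 0)

    def test_negative_velocity_rejected(self, row0_rates, constants):
        f1, g1, _ = row0_rates
        with pytest.raises(mt.InvalidInputError):
            mt.energy_rate(-1.0, f1, g1, 1.0, constants)


class TestTensionCurve:
    def test_isometric_equals_n_times_po(self, row0_rates, constants):
        f1, g1, g2 = row0_rates
        n = 3.19e10
        po_N = mt.unitary_force(f1, g1, constants) * 1e-12
        p0 = mt.tension_curve(0.0, f1, g1, g2, n, constants)
        assert p0 == pytest.approx(n * po_N * 1e3, rel=1e-12)

    def test_crossbridge_number_closure(self, row0_rates, constants):
        """With N = To/po the isometric model tension equals To."""
        f1, g1, g2 = row0_rates
        to = 51.0  # mN/mm^2
        po_N = mt.unitary_force(f1, g1, constants) * 1e-12
        n_cb = (to * 1e-3) / po_N
        assert n_cb == pytest.approx(3.19e10, rel=0.01)
        assert mt.tension_curve(0.0, f1, g1, g2, n_cb, constants) == \
            pytest.approx(to, rel=1e-12)

    def test_braces_value_at_phi(self, row0_rates, constants):
        """Independent scalar evaluation of the velocity braces at V = Φ."""
        f1, g1, g2 = row0_rates
        phi = _phi(f1, g1, constants)
        braces = 1 - (1 - np.exp(-1)) * (1 + 0.5 * ((f1 + g1) / g2) ** 2)
        p = mt.tension_curve(phi, f1, g1, g2, 1.0, constants)
        po_N = mt.unitary_force(f1, g1, constants) * 1e-12
        assert p == pytest.approx(po_N * 1e3 * braces, rel=1e-12)

    def test_strictly_decreasing_in_velocity(self, row0_rates, constants):
        f1, g1, g2 = row0_rates
        v = np.linspace(0, 2 * _phi(f1, g1, constants), 500)
        p = mt.tension_curve(v, f1, g1, g2, 1.0, constants)
        assert np.all(np.diff(p) < 0)

    def test_matches_brute_force_formula_on_random_draws(self, constants):
        """Vectorized curves agree with plain-python re-evaluation of the
        printed formulas to < 1e-12 relative on 1000 random draws."""
        import math
        rng = np.random.default_rng(11)
        for _ in range(1000):
            f1 = rng.uniform(100, 600)
            g1 = rng.uniform(50, 600)
            g2 = rng.uniform(200, 1200)
            phi = (f1 + g1) * constants.h / 2
            v = rng.uniform(1e-2, 3) * phi
            q = (v / phi) * (1 - math.exp(-phi / v))
            e_ref = constants.e * (constants.h / (2 * constants.l)) \
                * (f1 / (f1 + g1)) * (g1 + f1 * q)
            p_ref = (constants.w / (constants.l * 1e-9)) \
                * (f1 / (f1 + g1)) \
                * (1 - q * (1 + 0.5 * ((f1 + g1) / g2) ** 2 * (v / phi))) * 1e3
            assert abs(mt.energy_rate(v, f1, g1, 1.0, constants) / e_ref - 1) \
                < 1e-12
            p = mt.tension_curve(v, f1, g1, g2, 1.0, constants)
            assert abs(p - p_ref) <= 1e-12 * abs(p_ref) + 1e-300


class TestEfficiency:
    def test_control_maximum_matches_tabulated(self, row0_rates, constants):
        """Tabulated control efficiency is 28 ± 2 %."""
        f1, g1, g2 = row0_rates
        res = mt.efficiency_analysis(f1, g1, g2, constants)
        assert abs(100 * res.max_efficiency - 28.0) <= 2.0

    def test_against_dense_grid_oracle(self, row0_rates, constants):
        """Brute-force 10⁴-point grid maximization: η ≈ 0.297 at V/Φ ≈ 0.5."""
        f1, g1, g2 = row0_rates
        phi = _phi(f1, g1, constants)
        v = np.linspace(1e-3 * phi, 3 * phi, 10_000)
        p = mt.tension_curve(v, f1, g1, g2, 1.0, constants) * 1e-3
        e = mt.energy_rate(v, f1, g1, 1.0, constants)
        eta = p * (v * 1e-9) / e
        i = int(np.argmax(eta))
        res = mt.efficiency_analysis(f1, g1, g2, constants)
        assert res.max_efficiency == pytest.approx(eta[i], abs=1e-5)
        assert res.max_efficiency == pytest.approx(0.297, abs=0.002)
        assert res.v_opt / phi == pytest.approx(v[i] / phi, abs=0.01)
        assert res.v_opt / phi == pytest.approx(0.5, abs=0.02)

    def test_vanishes_at_both_ends(self, row0_rates, constants):
        f1, g1, g2 = row0_rates
        res = mt.efficiency_analysis(f1, g1, g2, constants)
        assert res.efficiency[0] < 0.01
        assert res.efficiency[0] < 0.05 * res.max_efficiency
        assert abs(res.efficiency[-1]) < 1e-6

    def test_bounded_by_work_fraction(self, row0_rates, constants):
        f1, g1, g2 = row0_rates
        res = mt.efficiency_analysis(f1, g1, g2, constants)
        assert 0 < res.max_efficiency < constants.w_over_e

    def test_independent_of_crossbridge_number_and_e_scale(self, row0_rates):
        """η is invariant to N (cancels) and to joint (e, w) rescaling
        at fixed w/e."""
        f1, g1, g2 = row0_rates
        base = mt.efficiency_analysis(f1, g1, g2).max_efficiency
        scaled_c = mt.CrossbridgeConstants(e=3e-19)  # w scales with e
        scaled = mt.efficiency_analysis(f1, g1, g2, scaled_c).max_efficiency
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_anoxia_degrades_max_efficiency(self, reference_anoxia, constants):
        """Efficiency computed from the 180-min rate constants is below
        the control value (tabulated trend 28% → 18%)."""
        r = reference_anoxia.set_index("time_min")
        eff = {}
        for t in (0, 180):
            eff[t] = mt.efficiency_analysis(
                r.loc[t, "f1_mean"], r.loc[t, "g1_mean"],
                r.loc[t, "g2_mean"], constants).max_efficiency
        assert eff[180] < eff[0]


class TestDeriveParams:
    def test_phi_equals_b_iff_curvature_three(self, constants):
        """Φ = (f1+g1)h/2 equals b exactly only at G = 3."""
        for g in (0.5, 1.0, 2.0, 3.0, 4.0, 8.0):
            b_nm = 2000.0
            f1, g1, _ = mt.rate_constants(g, b_nm, 3000.0, constants)
            phi = (f1 + g1) * constants.h / 2
            if g == 3.0:
                assert phi == pytest.approx(b_nm, rel=1e-12)
            else:
                assert abs(phi / b_nm - 1) > 1e-3

    def test_full_derivation_from_hill_fit(self, constants):
        ds = mt.sample_hyperbola(a=10, b=2.0, to=51)   # G = 5.1
        hf = mt.fit_hill(ds)
        cb = mt.derive_cb_params(hf, v0=5.1, myosin_content=13.9, c=constants,
                                 vmax_measured=3.8)
        # g2 closed on the measured Vmax, not the fitted one
        assert cb.g2 == pytest.approx(
            2 * constants.lo_per_s_to_nm_per_s(3.8) / constants.h, rel=1e-12)
        assert cb.n_cb == pytest.approx(
            (hf.to * 1e-3) / (cb.po * 1e-12), rel=1e-12)
        assert cb.ts == pytest.approx(constants.h / 5100.0, rel=1e-12)
        # ATPase / myosin content identity
        assert cb.atpase / cb.myosin_content == pytest.approx(cb.kcat,
                                                              rel=1e-12)
        assert cb.max_efficiency is not None
        assert cb.po <= constants.w_over_l_pN
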