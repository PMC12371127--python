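"""Forward-model tests: rate law, ramp integration, thermogram synthesis."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from thermopet.constants import R
from thermopet.kinetics import (
    ArrheniusTransition,
    DenaturationScheme,
    ScanRateSeries,
    StartTemperatureWarning,
    Thermogram,
    apparent_tm,
    arrhenius_rate,
    frequency_factor,
    simulate_states,
    simulate_thermogram,
)


def _transition(Ea=300e3, T_star=360.0, dH=400e3):
    return ArrheniusTransition("t", dH_cal=dH, Ea=Ea, T_star=T_star)


class TestArrheniusRate:
    def test_unity_at_reference_temperature(self):
        # "one molecule per second" at T = T*, whatever Ea
        for Ea in (1e5, 3e5, 6e5):
            assert arrhenius_rate(_transition(Ea=Ea), 360.0) == pytest.approx(1.0, abs=0)

    def test_vanishing_activation_energy_limit(self):
        tr = _transition(Ea=1e-6)
        for T in (300.0, 340.0, 420.0):
            assert arrhenius_rate(tr, T) == pytest.approx(1.0, rel=1e-9)

    def test_hand_evaluated_value(self):
        # exp(-(300000/8.314) * (1/350 - 1/360)) evaluated independently
        expected = np.exp(-(300e3 / R) * (1.0 / 350.0 - 1.0 / 360.0))
        assert expected == pytest.approx(0.0571, abs=2e-4)
        assert arrhenius_rate(_transition(), 350.0) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            arrhenius_rate(_transition(), 0.0)
        with pytest.raises(ValueError):
            arrhenius_rate(_transition(), np.array([350.0, -1.0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        Ea=st.floats(5e4, 1e6),
        T_star=st.floats(300.0, 420.0),
        T=st.floats(280.0, 430.0),
    )
    def test_strictly_increasing_in_temperature(self, Ea, T_star, T):
        tr = _transition(Ea=Ea, T_star=T_star)
        upper = arrhenius_rate(tr, T + 0.5)
        assume(upper < 1e11)  # below the numerical rate cap
        assert upper > arrhenius_rate(tr, T)


class TestFrequencyFactor:
    def test_log_identity_and_round_trip(self):
        tr = _transition(Ea=300e3, T_star=360.0)
        ln_a = np.log(frequency_factor(tr))
        assert ln_a == pytest.approx(300e3 / (R * 360.0), rel=1e-12)
        assert ln_a == pytest.approx(100.24, abs=0.01)
        # inverse relation: T* = Ea / (R ln A)
        assert 300e3 / (R * ln_a) == pytest.approx(360.0, rel=1e-9)


class TestTypeInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dH_cal": -1.0, "Ea": 3e5, "T_star": 350.0},
            {"dH_cal": 4e5, "Ea": 0.0, "T_star": 350.0},
            {"dH_cal": 4e5, "Ea": 3e5, "T_star": 200.0},  # below window
            {"dH_cal": 4e5, "Ea": 3e5, "T_star": 500.0},  # above window
        ],
    )
    def test_invalid_transition_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ArrheniusTransition("bad", **kwargs)

    def test_scheme_shape_enforced(self, one_step_scheme):
        with pytest.raises(ValueError):
            DenaturationScheme("irreversible_two_step", transitions=one_step_scheme.transitions)
        with pytest.raises(ValueError):
            DenaturationScheme("reversible_two_state", transitions=one_step_scheme.transitions)

    def test_series_needs_distinct_rates(self, two_step_scheme, grid_50_100C):
        tg = simulate_thermogram(
            two_step_scheme, 1.0, grid_50_100C, on_start_violation="ignore"
        )
        with pytest.raises(ValueError):
            ScanRateSeries("e", (tg,))
        with pytest.raises(ValueError):
            ScanRateSeries("simulated", (tg, tg))


class TestSimulateStates:
    def test_no_flux_far_below_transition(self, two_step_scheme):
        T = np.linspace(280.0, 300.0, 50)
        st_ = simulate_states(two_step_scheme, 1.0, T)
        assert np.all(st_.x_N > 1 - 1e-9)

    def test_conservation_and_monotonicity(self, two_step_scheme, grid_50_100C):
        st_ = simulate_states(
            two_step_scheme, 0.8, grid_50_100C, on_start_violation="ignore"
        )
        total = st_.x_N + st_.x_I + st_.x_D
        assert np.max(np.abs(total - 1.0)) < 1e-6
        assert np.all(np.diff(st_.x_N) <= 1e-12)
        assert np.all(np.diff(st_.x_D) >= -1e-12)
        # the intermediate actually populates then clears
        assert st_.x_I.max() > 0.05
        assert st_.x_I[-1] < 1e-3

    def test_one_step_matches_fixed_step_euler(self, one_step_scheme):
        T = np.arange(320.0, 360.0 + 1e-9, 0.1)
        st_ = simulate_states(one_step_scheme, 1.0, T, on_start_violation="ignore")
        # brute-force oracle: forward Euler at 1e5 steps
        tr = one_step_scheme.transitions[0]
        n = 100_000
        fine = np.linspace(T[0], T[-1], n + 1)
        h = fine[1] - fine[0]
        k = arrhenius_rate(tr, fine) / (1.0 / 60.0)
        x = np.empty(n + 1)
        x[0] = 1.0
        for i in range(n):
            x[i + 1] = max(x[i] * (1.0 - h * k[i]), 0.0)
        oracle = np.interp(T, fine, x)
        assert np.max(np.abs(st_.x_N - oracle)) < 1e-4

    def test_two_step_matches_fixed_step_rk4(self):
        """Oracle equivalence on 20 randomized parameter draws."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(20):
            t1 = rng.uniform(350.0, 358.0)
            scheme = DenaturationScheme(
                "irreversible_two_step",
                transitions=(
                    ArrheniusTransition("1", dH_cal=4e5, Ea=rng.uniform(3e5, 6e5), T_star=t1),
                    ArrheniusTransition("2", dH_cal=1e5, Ea=rng.uniform(2.5e5, 5e5),
                                        T_star=t1 + rng.uniform(3.0, 10.0)),
                ),
            )
            v = rng.choice([0.2, 0.8, 3.2]) / 60.0
            T = np.arange(323.15, 373.15, 0.25)
            st_ = simulate_states(scheme, v * 60.0, T, on_start_violation="ignore")
            n = 100_000
            fine = np.linspace(T[0], T[-1], n + 1)
            h = fine[1] - fine[0]
            k1 = arrhenius_rate(scheme.transitions[0], fine) / v
            k2 = arrhenius_rate(scheme.transitions[1], fine) / v
            k1m = 0.5 * (k1[:-1] + k1[1:])
            k2m = 0.5 * (k2[:-1] + k2[1:])
            xn, xi = 1.0, 0.0
            xn_path = np.empty(n + 1)
            xi_path = np.empty(n + 1)
            xn_path[0], xi_path[0] = xn, xi

            for i in range(n):
                def f(y, a, b):
                    return np.array([-a * y[0], a * y[0] - b * y[1]])

                y = np.array([xn, xi])
                s1 = f(y, k1[i], k2[i])
                s2 = f(y + 0.5 * h * s1, k1m[i], k2m[i])
                s3 = f(y + 0.5 * h * s2, k1m[i], k2m[i])
                s4 = f(y + h * s3, k1[i + 1], k2[i + 1])
                y = y + h / 6.0 * (s1 + 2 * s2 + 2 * s3 + s4)
                xn, xi = max(y[0], 0.0), max(y[1], 0.0)
                xn_path[i + 1], xi_path[i + 1] = xn, xi
            worst = max(
                worst,
                np.max(np.abs(st_.x_N - np.interp(T, fine, xn_path))),
                np.max(np.abs(st_.x_I - np.interp(T, fine, xi_path))),
            )
        assert worst < 1e-4

    def test_grid_validation(self, two_step_scheme):
        with pytest.raises(ValueError):
            simulate_states(two_step_scheme, 1.0, np.array([350.0, 349.0, 351.0]))
        with pytest.raises(ValueError):
            simulate_states(two_step_scheme, -1.0, np.linspace(320, 370, 100))

    def test_start_precondition_warns_or_errors(self, two_step_scheme):
        T = np.linspace(345.0, 373.0, 100)  # starts inside the transition
        with pytest.warns(StartTemperatureWarning):
            simulate_states(two_step_scheme, 0.2, T)
        with pytest.raises(ValueError):
            simulate_states(two_step_scheme, 0.2, T, on_start_violation="error")


class TestSimulateThermogram:
    def test_enthalpy_conservation(self, two_step_scheme, grid_50_100C):
        for v in (0.2, 3.2):
            tg = simulate_thermogram(
                two_step_scheme, v, grid_50_100C, on_start_violation="ignore"
            )
            assert np.all(tg.cp_excess >= 0)
            assert tg.area == pytest.approx(two_step_scheme.total_enthalpy, rel=5e-3)

    def test_reversible_curves_independent_of_scan_rate(self, reversible_scheme):
        T = np.arange(323.15, 373.15, 0.1)
        slow = simulate_thermogram(reversible_scheme, 0.2, T)
        fast = simulate_thermogram(reversible_scheme, 3.2, T)
        np.testing.assert_allclose(slow.cp_excess, fast.cp_excess, rtol=1e-12)
        assert apparent_tm(slow) == pytest.approx(apparent_tm(fast), abs=1e-9)
        assert slow.area == pytest.approx(reversible_scheme.total_enthalpy, rel=5e-3)

    def test_one_step_peak_increases_with_scan_rate(self, one_step_scheme):
        T = np.arange(313.15, 368.15, 0.1)
        tms = [
            apparent_tm(
                simulate_thermogram(one_step_scheme, v, T, on_start_violation="ignore")
            )
            for v in (0.2, 0.4, 0.8, 1.6, 3.2)
        ]
        assert np.all(np.diff(tms) > 0)
        # a 16-fold rate increase shifts the peak by several degrees
        assert tms[-1] - tms[0] > 3.0

    def test_deconvolution_components_sum(self, two_step_scheme, grid_50_100C):
        tg, comps = simulate_thermogram(
            two_step_scheme, 1.0, grid_50_100C,
            on_start_violation="ignore", components=True,
        )
        assert len(comps) == 2
        np.testing.assert_allclose(np.sum(comps, axis=0), tg.cp_excess, rtol=1e-12)


class TestApparentTm:
    def test_symmetric_synthetic_peak(self):
        T = np.arange(330.0, 366.0, 0.25)
        cp = 5e4 * np.exp(-((T - 348.15) ** 2) / 8.0)
        tg = Thermogram("e", 1.0, T, cp)
        assert apparent_tm(tg) == pytest.approx(348.15, abs=0.25)

    def test_one_step_peak_condition(self, one_step_scheme):
        """At the maximum, k(Tm) = v Ea / (R Tm^2) (closed-form peak law)."""
        tr = one_step_scheme.transitions[0]
        T = np.arange(313.15, 368.15, 0.05)
        for v in (0.2, 1.0, 3.2):
            tm = apparent_tm(
                simulate_thermogram(one_step_scheme, v, T, on_start_violation="ignore")
            )
            lhs = arrhenius_rate(tr, tm)
            rhs = (v / 60.0) * tr.Ea / (R * tm**2)
            assert lhs == pytest.approx(rhs, rel=0.01)

    def test_scan_rate_law_recovers_activation_energy(self, one_step_scheme):
        """Regressing ln(v/Tm^2) on 1/Tm gives slope -Ea/R within 1%."""
        tr = one_step_scheme.transitions[0]
        T = np.arange(313.15, 368.15, 0.05)
        rates = np.array([0.2, 0.4, 0.8, 1.6, 3.2])
        tms = np.array([
            apparent_tm(
                simulate_thermogram(one_step_scheme, v, T, on_start_violation="ignore")
            )
            for v in rates
        ])
        slope = np.polyfit(1.0 / tms, np.log((rates / 60.0) / tms**2), 1)[0]
        assert -slope * R == pytest.approx(tr.Ea, rel=0.01)

    def test_boundary_and_flat_rejected(self):
        T = np.arange(330.0, 340.0, 0.5)
        rising = Thermogram("e", 1.0, T, np.linspace(0, 1e4, T.size))
        with pytest.raises(ValueError):
            apparent_tm(rising)
        flat = Thermogram("e", 1.0, T, np.full(T.size, 5.0))
        with pytest.raises(ValueError):
            apparent_tm(flat)
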