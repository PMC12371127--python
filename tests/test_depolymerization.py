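"""Depolymerization readouts: totals, conversion, rates, pH-stat, retention."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermopet.depolymerization import (
    QualityFlagWarning,
    ReactionCondition,
    RetentionAssay,
    TimeCourse,
    TitrationTrace,
    bhet_equivalents,
    conversion_fraction,
    fold_change,
    initial_rate,
    mass_loss_percent,
    phstat_hydrolysis,
    retained_fraction,
    total_aromatic_products,
)

M_REPEAT = 192.17


def _tc(rows, unit="mM", loading=None, enzyme_id="E"):
    cond = ReactionCondition(pet_loading_pct_wv=loading)
    return TimeCourse(enzyme_id, pd.DataFrame(rows), unit, cond)


class TestTotalAromaticProducts:
    def test_hand_computed_molar_and_mass_totals(self):
        tc = _tc([{"time_h": 1.0, "tpa": 1.0, "mhet": 2.0, "bhet": 3.0}])
        out = total_aromatic_products(tc)
        assert out["total_mM"].iloc[0] == pytest.approx(6.0, rel=1e-12)
        # 1*0.16613 + 2*0.21018 + 3*0.25424 g/L
        assert out["total_g_per_L"].iloc[0] == pytest.approx(1.34921, abs=1e-5)

    def test_zeros_and_single_species(self):
        zero = _tc([{"time_h": 0.0, "tpa": 0.0, "mhet": 0.0, "bhet": 0.0}])
        assert total_aromatic_products(zero)["total_mM"].iloc[0] == 0.0
        only_tpa = _tc([{"time_h": 1.0, "tpa": 4.0, "mhet": 0.0, "bhet": 0.0}])
        assert total_aromatic_products(only_tpa)["total_mM"].iloc[0] == 4.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        tpa=st.floats(0, 30), mhet=st.floats(0, 30), bhet=st.floats(0, 5)
    )
    def test_unit_round_trip(self, tpa, mhet, bhet):
        tc = _tc([{"time_h": 1.0, "tpa": tpa, "mhet": mhet, "bhet": bhet}], unit="g_per_L")
        back = tc.in_unit("mM").in_unit("g_per_L")
        for col, val in (("tpa", tpa), ("mhet", mhet), ("bhet", bhet)):
            assert back.data[col].iloc[0] == pytest.approx(val, rel=1e-9, abs=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            _tc([{"time_h": 0.0, "tpa": -1.0, "mhet": 0.0, "bhet": 0.0}])


class TestConversionFraction:
    def test_complete_conversion(self):
        total_mM = 29.0 / M_REPEAT * 1e3  # all repeat units of 2.9% w/v
        tc = _tc([{"time_h": 24.0, "tpa": total_mM, "mhet": 0.0, "bhet": 0.0}],
                 loading=2.9)
        assert conversion_fraction(tc)["conversion"].iloc[0] == pytest.approx(1.0, rel=1e-9)

    def test_half_and_hand_computed(self):
        half = 0.5 * 29.0 / M_REPEAT * 1e3
        tc = _tc([{"time_h": 8.0, "tpa": half, "mhet": 0.0, "bhet": 0.0}], loading=2.9)
        assert conversion_fraction(tc)["conversion"].iloc[0] == pytest.approx(0.5, rel=1e-9)
        tc2 = _tc([{"time_h": 8.0, "tpa": 20.0, "mhet": 0.0, "bhet": 0.0}],
                  unit="g_per_L", loading=2.9)
        # 20 g/L TPA = 0.12039 M aromatic vs 0.15091 M theoretical
        assert conversion_fraction(tc2)["conversion"].iloc[0] == pytest.approx(0.798, abs=2e-3)

    def test_invariant_to_unit_choice(self):
        tc = _tc([{"time_h": 8.0, "tpa": 10.0, "mhet": 5.0, "bhet": 1.0}],
                 unit="g_per_L", loading=2.9)
        a = conversion_fraction(tc)["conversion"].iloc[0]
        b = conversion_fraction(tc.in_unit("mM"))["conversion"].iloc[0]
        assert a == pytest.approx(b, rel=1e-12)

    def test_missing_loading_errors(self):
        tc = _tc([{"time_h": 8.0, "tpa": 1.0, "mhet": 0.0, "bhet": 0.0}])
        with pytest.raises(ValueError, match="loading"):
            conversion_fraction(tc)

    def test_overrange_clipped_and_flagged(self):
        too_much = 2.0 * 29.0 / M_REPEAT * 1e3
        tc = _tc([{"time_h": 48.0, "tpa": too_much, "mhet": 0.0, "bhet": 0.0}], loading=2.9)
        with pytest.warns(QualityFlagWarning):
            out = conversion_fraction(tc)
        assert out["conversion"].iloc[0] == 1.02


class TestInitialRate:
    def test_exact_line(self):
        rows = [{"time_h": t, "tpa": 2.5 * t, "mhet": 0.0, "bhet": 0.0}
                for t in (0, 2, 4, 6, 8)]
        rate = initial_rate(_tc(rows, unit="g_per_L"), window_end=8.0)
        assert rate.g_per_L_h == pytest.approx(2.5, rel=1e-12)
        assert rate.n_points == 5

    def test_constant_product_zero_rate(self):
        rows = [{"time_h": t, "tpa": 3.0, "mhet": 0.0, "bhet": 0.0} for t in (0, 4, 8)]
        assert initial_rate(_tc(rows, unit="g_per_L"), 8.0).g_per_L_h == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_errors(self):
        rows = [{"time_h": 0.0, "tpa": 0.0, "mhet": 0.0, "bhet": 0.0},
                {"time_h": 24.0, "tpa": 9.0, "mhet": 0.0, "bhet": 0.0}]
        with pytest.raises(ValueError):
            initial_rate(_tc(rows, unit="g_per_L"), window_end=8.0)

    def test_recovers_generator_rate_when_inactivation_is_slow(self):
        from thermopet.synthetic import gen_timecourse

        tc = gen_timecourse(r0=2.0, k_inact=1e-9, mhet_to_tpa_rate=0.1,
                            theoretical_max=1e6, times=(0, 2, 4, 6, 8),
                            noise_sd=0.0, replicates=1)
        assert initial_rate(tc, 8.0).g_per_L_h == pytest.approx(2.0, rel=0.01)


class TestFoldChange:
    def _pair(self, factor):
        ref_rows = [{"replicate": r, "time_h": t, "tpa": 1.0 * t, "mhet": 0.0, "bhet": 0.0}
                    for r in (1, 2) for t in (0, 6, 24)]
        var_rows = [{"replicate": r, "time_h": t, "tpa": factor * t, "mhet": 0.0, "bhet": 0.0}
                    for r in (1, 2) for t in (0, 6, 24)]
        return _tc(var_rows, unit="g_per_L", enzyme_id="var"), _tc(ref_rows, unit="g_per_L")

    def test_identical_tables_unity(self):
        var, ref = self._pair(1.0)
        assert fold_change(ref, ref, 6.0).ratio == pytest.approx(1.0, rel=1e-12)

    def test_doubled_variant(self):
        var, ref = self._pair(2.0)
        for t in (6.0, 24.0):
            assert fold_change(var, ref, t).ratio == pytest.approx(2.0, rel=1e-12)

    def test_ratio_matches_reported_form(self):
        var, ref = self._pair(1.97)
        fc = fold_change(var, ref, 6.0)
        assert fc.ratio == pytest.approx(1.97, rel=1e-12)
        assert fc.sd >= 0.0

    def test_missing_timepoint_needs_interpolation_flag(self):
        var, ref = self._pair(2.0)
        with pytest.raises(ValueError, match="interpolate"):
            fold_change(var, ref, 5.0)
        assert fold_change(var, ref, 5.0, interpolate=True).ratio == pytest.approx(2.0, rel=1e-12)


class TestBhetEquivalents:
    def test_exact_linear_inversion(self):
        stds_c = np.array([0.5, 1.0, 2.0, 4.0])
        conc = bhet_equivalents([1.0], stds_c, 0.5 * stds_c)
        assert conc[0] == pytest.approx(2.0, rel=1e-12)

    def test_baseline_subtraction(self):
        stds_c = np.array([0.5, 1.0, 2.0, 4.0])
        conc = bhet_equivalents([0.3], stds_c, 0.5 * stds_c, baseline=0.3)
        assert conc[0] == pytest.approx(0.0, abs=1e-12)

    def test_serial_dilution_with_noise_recovers_within_3pct(self):
        rng = np.random.default_rng(3)
        stds_c = 8.0 / 2 ** np.arange(6)  # 2-fold serial dilution
        true_slope = 0.45
        stds_a = true_slope * stds_c * (1 + rng.normal(0, 0.01, stds_c.size))
        samples_c = np.array([1.5, 3.0, 6.0])
        out = bhet_equivalents(true_slope * samples_c, stds_c, stds_a)
        np.testing.assert_allclose(out, samples_c, rtol=0.03)

    def test_non_monotone_standards_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            bhet_equivalents([1.0], [1.0, 2.0, 3.0], [0.5, 1.5, 1.0])


class TestPhstatHydrolysis:
    def test_theoretical_volume_for_5_8_g(self):
        """2 * (5.8 g / 192.17 g/mol) / 6 M = 10.06 mL at 100%."""
        v100 = 2.0 * (5.8 / M_REPEAT) / 6.0 * 1e3
        assert v100 == pytest.approx(10.06, abs=0.01)
        trace = TitrationTrace(
            times=np.array([0.0, 24.0, 48.0]),
            cumulative_base_volume=np.array([0.0, v100 / 2.0, v100]),
            base_molarity=6.0,
            pet_mass=5.8,
        )
        pct = phstat_hydrolysis(trace)["hydrolysis_pct"]
        assert pct.iloc[0] == 0.0
        assert pct.iloc[1] == pytest.approx(50.0, rel=1e-9)
        assert pct.iloc[2] == pytest.approx(100.0, rel=1e-9)

    @pytest.mark.filterwarnings("ignore::thermopet.depolymerization.QualityFlagWarning")
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 3.0), mass=st.floats(1.0, 40.0))
    def test_linear_in_volume_homogeneous_in_mass(self, scale, mass):
        t = np.array([0.0, 10.0])
        v = np.array([0.0, 4.0])
        base = phstat_hydrolysis(
            TitrationTrace(t, v, base_molarity=6.0, pet_mass=mass)
        )["hydrolysis_pct"].iloc[-1]
        scaled_v = phstat_hydrolysis(
            TitrationTrace(t, v * scale, base_molarity=6.0, pet_mass=mass)
        )["hydrolysis_pct"].iloc[-1]
        scaled_m = phstat_hydrolysis(
            TitrationTrace(t, v, base_molarity=6.0, pet_mass=mass * scale)
        )["hydrolysis_pct"].iloc[-1]
        assert scaled_v == pytest.approx(base * scale, rel=1e-9)
        assert scaled_m == pytest.approx(base / scale, rel=1e-9)

    def test_decreasing_volume_rejected(self):
        with pytest.raises(ValueError):
            TitrationTrace(np.array([0.0, 1.0]), np.array([2.0, 1.0]), 6.0, 5.8)


class TestMassLossAndRetention:
    @pytest.mark.parametrize(
        "initial,residual,expected",
        [(5.8, 0.203, 96.5), (5.8, 5.8, 0.0), (5.8, 0.0, 100.0)],
    )
    def test_mass_loss(self, initial, residual, expected):
        assert mass_loss_percent(initial, residual) == pytest.approx(expected, abs=0.05)

    def test_salt_carry_over_flagged(self):
        with pytest.warns(QualityFlagWarning, match="carry-over"):
            value = mass_loss_percent(5.8, 6.0)
        assert value < 0  # reported as-is

    @pytest.mark.parametrize(
        "treated,expected",
        [(8000.0, 0.789), (10000.0, 1.0), (500.0, 0.0)],
    )
    def test_retained_fraction(self, treated, expected):
        assay = RetentionAssay(
            fluorescence_initial=10000.0,
            fluorescence_treated=treated,
            fluorescence_background=500.0,
        )
        assert retained_fraction(assay) == pytest.approx(expected, abs=1e-3)

    def test_background_above_initial_rejected(self):
        with pytest.raises(ValueError):
            RetentionAssay(100.0, 50.0, 200.0)
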