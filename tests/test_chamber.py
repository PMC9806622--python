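"""Gas-exchange reduction: flux formulas, visit averaging, baseline correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pinehydro import chamber


class TestMolarFlow:
    def test_zero_flow(self):
        assert chamber.molar_flow(0, 25, 101.325) == 0.0

    def test_ten_liters_per_minute(self):
        # ideal gas: 101325 Pa * (10/60000) m^3/s / (R * 298.15 K)
        assert chamber.molar_flow(10, 25, 101.325) == pytest.approx(6.813e-3, rel=1e-3)

    def test_linear_in_pressure(self):
        assert chamber.molar_flow(5, 20, 200) == pytest.approx(
            2 * chamber.molar_flow(5, 20, 100)
        )

    @pytest.mark.parametrize("bad", [(np.nan, 25, 100), (1, -300, 100), (1, 25, 0)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            chamber.molar_flow(*bad)


class TestSaturation:
    def test_buck_at_zero_celsius(self):
        assert chamber.saturation_vapor_pressure(0.0) == pytest.approx(0.6112, abs=1e-4)
        assert chamber.saturation_mole_fraction(0.0, 101.325) == pytest.approx(
            6.03e-3, rel=1e-3
        )

    def test_buck_at_24_celsius(self):
        assert chamber.saturation_mole_fraction(24.0, 101.325) == pytest.approx(
            0.0294, abs=2e-4
        )

    def test_monotone_in_temperature(self):
        t = np.linspace(-10, 50, 61)
        w = chamber.saturation_mole_fraction(t, 101.325)
        assert np.all(np.diff(w) > 0)

    def test_tetens_close_to_buck(self):
        b = chamber.saturation_vapor_pressure(20.0, "buck")
        t = chamber.saturation_vapor_pressure(20.0, "tetens")
        assert b == pytest.approx(t, rel=0.005)

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(ValueError):
            chamber.saturation_mole_fraction(20.0, 0.0)


class TestFluxes:
    def test_no_water_added_means_zero_e(self):
        assert chamber.transpiration(6.8e-3, 0.01, 0.01, 0.05) == 0.0

    def test_transpiration_hand_value(self):
        e = chamber.transpiration(6.8e-3, 0.010, 0.012, 0.05)
        assert e == pytest.approx(2.753e-4, rel=1e-3)

    def test_halving_leaf_area_doubles_e(self):
        e1 = chamber.transpiration(6.8e-3, 0.010, 0.012, 0.05)
        e2 = chamber.transpiration(6.8e-3, 0.010, 0.012, 0.025)
        assert e2 == pytest.approx(2 * e1)

    def test_zero_flux_zero_conductance(self):
        assert chamber.canopy_conductance(0.0, 0.03, 0.01) == 0.0

    def test_conductance_hand_value(self):
        gc = chamber.canopy_conductance(2.753e-4, 0.0294, 0.012)
        assert gc == pytest.approx(0.0155, abs=1e-4)

    def test_saturated_air_returns_nan_not_exception(self):
        assert np.isnan(chamber.canopy_conductance(1e-4, 0.02, 0.025))

    def test_invalid_leaf_area(self):
        with pytest.raises(ValueError):
            chamber.transpiration(1e-3, 0.01, 0.012, 0.0)

    @settings(deadline=None, max_examples=200)
    @given(
        fm=st.floats(1e-4, 1e-1),
        ws=st.floats(1e-4, 0.02),
        dw=st.floats(1e-6, 0.01),
        al=st.floats(1e-3, 1.0),
        t=st.floats(5.0, 40.0),
    )
    def test_composition_matches_single_expression(self, fm, ws, dw, al, t):
        """E then gc equals the one-shot algebraic composition to 1e-12."""
        w_sample = ws + dw
        w_leaf = chamber.saturation_mole_fraction(t, 101.325)
        if w_leaf <= w_sample:
            return
        e = chamber.transpiration(fm, ws, w_sample, al)
        gc = chamber.canopy_conductance(e, w_leaf, w_sample)
        oracle = (
            fm * (w_sample - ws) / (al * (1 - w_sample))
            * (1 - (w_leaf + w_sample) / 2) / (w_leaf - w_sample)
        )
        assert gc == pytest.approx(oracle, rel=1e-12)


def _stream(values, chamber_id="c1", t0=0.0, cadence=10.0, is_empty=False):
    n = len(values)
    return pd.DataFrame(
        {
            "chamber_id": chamber_id,
            "time_s": t0 + cadence * np.arange(1, n + 1),
            "w_supply": 0.008,
            "w_sample": values,
            "co2_supply": 400.0,
            "co2_sample": 380.0,
            "flow_lpm": 10.0,
            "t_air_c": 24.0,
            "pressure_kpa": 101.325,
            "par": 500.0,
            "is_empty": is_empty,
        }
    )


class TestCycleReduce:
    def test_constant_stream_preserved(self):
        df = _stream([0.01] * 12)
        out = chamber.cycle_reduce(df)
        assert len(out) == 1
        assert out["w_sample"].iloc[0] == pytest.approx(0.01)

    def test_last_window_mean(self):
        # 120-s visit of 10-s records valued 1..12 -> mean of last 4 is 10.5
        df = _stream(np.arange(1, 13) * 1e-3)
        out = chamber.cycle_reduce(df, chamber.GasExchangeConfig(window=40))
        assert out["w_sample"].iloc[0] == pytest.approx(10.5e-3)
        assert out["n_records"].iloc[0] == 4

    def test_visit_count_and_cadence(self):
        # two chambers alternating 120-s visits over 4 cycles
        frames = []
        for cyc in range(4):
            for ci, cid in enumerate(["c1", "c2"]):
                frames.append(
                    _stream([0.01] * 12, chamber_id=cid, t0=240.0 * cyc + 120.0 * ci)
                )
        out = chamber.cycle_reduce(pd.concat(frames, ignore_index=True))
        assert len(out) == 8
        c1 = out[out["chamber_id"] == "c1"]["time_s"].to_numpy()
        assert np.allclose(np.diff(c1), 240.0)  # n_chambers * switch_period

    def test_absent_chamber_gives_no_rows(self):
        out = chamber.cycle_reduce(_stream([0.01] * 12, chamber_id="c1"))
        assert not (out["chamber_id"] == "c2").any()

    def test_short_visit_uses_available_records(self, caplog):
        df = _stream([1e-3, 2e-3])  # 20 s of records < 40 s window
        with caplog.at_level("WARNING"):
            out = chamber.cycle_reduce(df)
        assert out["w_sample"].iloc[0] == pytest.approx(1.5e-3)

    def test_nonmonotonic_time_rejected(self):
        df = _stream([0.01] * 4)
        df.loc[2, "time_s"] = df.loc[1, "time_s"]
        with pytest.raises(ValueError, match="strictly increasing"):
            chamber.cycle_reduce(df)


class TestBaselineCorrect:
    def test_zero_offset_is_identity(self):
        t = np.arange(5.0)
        dw = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = chamber.baseline_correct(t, dw, [(t, np.zeros(5))])
        np.testing.assert_allclose(out, dw)

    def test_constant_offset_shift(self):
        t = np.arange(5.0)
        dw = np.ones(5)
        out = chamber.baseline_correct(t, dw, [(t, np.full(5, 0.3))])
        np.testing.assert_allclose(out, 0.7)

    def test_mean_of_two_empties(self):
        # offsets 0.02 and 0.04 ppt -> 0.03 ppt subtracted
        t = np.arange(5.0)
        dw = np.full(5, 0.1e-3)
        out = chamber.baseline_correct(
            t, dw, [(t, np.full(5, 0.02e-3)), (t, np.full(5, 0.04e-3))]
        )
        np.testing.assert_allclose(out, 0.07e-3)

    def test_missing_empties_instructive_error(self):
        with pytest.raises(ValueError, match="baseline_correction=False"):
            chamber.baseline_correct(np.arange(3.0), np.ones(3), [])
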