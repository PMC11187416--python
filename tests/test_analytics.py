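"""Deviation integral, fold reduction, soft sensor, yield comparison."""

import math

import numpy as np
import pytest

import mirferm as mf
from mirferm.errors import InsufficientDataError


class TestCumulativeDeviation:
    def test_constant_at_setpoint_is_zero(self):
        t = np.arange(0.0, 49.0, 1.0)
        dev = mf.cumulative_deviation(t, np.full_like(t, 20.0), 20.0)
        assert dev.total == 0.0

    def test_constant_offset_rectangle_area(self):
        t = np.arange(0.0, 49.0, 1.0)
        dev = mf.cumulative_deviation(t, np.full_like(t, 21.0), 20.0, window=48.0)
        assert dev.total == pytest.approx(48.0)

    def test_absolute_not_signed(self):
        t = np.arange(0.0, 48.1, 0.5)
        v = np.where(t < 24.0, 21.0, 19.0)
        dev = mf.cumulative_deviation(t, v, 20.0, window=48.0)
        assert dev.total == pytest.approx(48.0)

    def test_running_total_monotone_nondecreasing(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0.0, 48.0, 200))
        v = 20.0 + rng.normal(0.0, 2.0, 200)
        dev = mf.cumulative_deviation(t, v, 20.0)
        assert np.all(np.diff(dev.running_total) >= 0.0)

    def test_additive_over_contiguous_subwindows(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 48.0, 0.25)
        v = 20.0 + rng.normal(0.0, 2.0, len(t))
        whole = mf.cumulative_deviation(t, v, 20.0, window=48.0, t0=0.0)
        first = mf.cumulative_deviation(t, v, 20.0, window=24.0, t0=0.0)
        m = t >= 24.0
        second = mf.cumulative_deviation(t[m], v[m], 20.0, window=24.0, t0=24.0)
        assert first.total + second.total == pytest.approx(whole.total, rel=1e-12)

    def test_duplicate_time_points_add_nothing(self):
        t = np.array([0.0, 1.0, 2.0, 48.0])
        v = np.array([21.0, 21.0, 21.0, 21.0])
        base = mf.cumulative_deviation(t, v, 20.0, window=48.0)
        t2 = np.array([0.0, 1.0, 1.0, 2.0, 48.0])
        v2 = np.array([21.0, 99.0, 21.0, 21.0, 21.0])  # zero-width spike
        dup = mf.cumulative_deviation(t2, v2, 20.0, window=48.0)
        assert dup.total == pytest.approx(base.total)

    def test_needs_two_points_in_window(self):
        with pytest.raises(InsufficientDataError):
            mf.cumulative_deviation([0.0], [21.0], 20.0)


class TestFoldReduction:
    def test_division(self):
        assert mf.fold_reduction(200.0, 10.0) == pytest.approx(20.0)

    def test_identity(self):
        assert mf.fold_reduction(7.0, 7.0) == 1.0

    def test_zero_denominator_flagged_infinite(self):
        assert math.isinf(mf.fold_reduction(5.0, 0.0))

    def test_reciprocal_property(self):
        assert mf.fold_reduction(3.0, 7.0) * mf.fold_reduction(7.0, 3.0) == \
            pytest.approx(1.0)


class TestConsumptionRate:
    def test_pure_depletion(self):
        assert mf.consumption_rate(30.0, 1.0, 29.5, 1.0, 0.0, 0.6, 0.5) == \
            pytest.approx(1.0)

    def test_with_feed_and_dilution(self):
        # (20*1 - 20*1.01 + 10*0.6)/0.5 = 11.6 g/h
        assert mf.consumption_rate(20.0, 1.0, 20.0, 1.01, 10.0, 0.6, 0.5) == \
            pytest.approx(11.6)

    def test_static_inputs_zero(self):
        assert mf.consumption_rate(20.0, 1.0, 20.0, 1.0, 0.0, 0.6, 0.5) == 0.0

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            mf.consumption_rate(20.0, 1.0, 19.0, 1.0, 0.0, 0.6, 0.0)


class TestSoftSensorSeries:
    def test_matches_plant_mass_balance_on_noiseless_run(self, auto_runlog):
        # per-interval C_t must track the plant's true q*X*V averaged over the
        # interval within 2% once the loop is running
        ss = mf.soft_sensor_series(auto_runlog, "glucose", 0.6)
        ticks = auto_runlog[(auto_runlog.event == "tick")
                            & (auto_runlog.analyte == "glucose")]
        t = ticks.time_h.to_numpy()
        cons = 0.08 * ticks.X_g_per_L.to_numpy() * ticks.V_L.to_numpy()
        late = ss[ss.t_h > 24.0]
        assert len(late) > 100
        for row in late.itertuples():
            m = (t >= row.t_h - row.I_h - 1e-9) & (t < row.t_h - 1e-9)
            truth = cons[m].mean()
            assert row.C_g_per_h == pytest.approx(truth, rel=0.02)

    def test_exact_on_true_state_when_biomass_constant(self):
        # frozen biomass: applied to the true state, the soft-sensor formula
        # inverts the Euler bookkeeping exactly (equality to ~1e-9)
        plant = mf.PlantParams(mu=0.0, X0=10.0)
        ctrl = {"glucose": mf.ControllerConfig(), "glutamate": mf.ControllerConfig()}
        log = mf.run_closed_loop(plant, mf.NOISELESS, ctrl,
                                 mf.ControlRegime(mode="auto"), horizon=48.0,
                                 seed=0)
        glc = log[log.analyte == "glucose"]
        ticks = glc[glc.event == "tick"]
        t = ticks.time_h.to_numpy()
        rate = ticks.pump_rate_mL_per_h.to_numpy()
        cons = 0.08 * ticks.X_g_per_L.to_numpy() * ticks.V_L.to_numpy()
        meas = glc[glc.event == "measurement"]
        tm = meas.time_h.to_numpy()
        g_true = meas.true_g_per_L.to_numpy()
        v = meas.V_L.to_numpy()
        dt = 1.0 / 60.0
        for k in range(250, len(tm), 17):
            interval = tm[k] - tm[k - 1]
            m = (t >= tm[k - 1] - 1e-9) & (t < tm[k] - 1e-9)
            pumped = float(np.sum(rate[m]) * dt)
            c_t = mf.consumption_rate(g_true[k - 1], v[k - 1], g_true[k], v[k],
                                      pumped, 0.6, interval)
            assert c_t == pytest.approx(cons[m].mean(), abs=1e-9)


class TestYieldSummary:
    def test_identical_groups_null_difference(self):
        res = mf.yield_summary({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res["t_statistic"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_shift_moves_mean_difference(self):
        res = mf.yield_summary({"a": [11.0, 12.0, 13.0], "b": [1.0, 2.0, 3.0]})
        assert res["mean_difference"] == pytest.approx(10.0)

    def test_welch_hand_computed(self):
        # means 11 vs 110, variances 2 and 200, n=2 each:
        # t = (11-110)/sqrt(2/2 + 200/2) = -99/sqrt(101)
        res = mf.yield_summary({"low": [10.0, 12.0], "high": [100.0, 120.0]})
        assert res["t_statistic"] == pytest.approx(-99.0 / math.sqrt(101.0))
        assert 0.0 < res["p_value"] < 0.2

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            mf.yield_summary({"a": [1.0], "b": [1.0, 2.0]})
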