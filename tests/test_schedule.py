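"""Exposure-schedule design: discretization, regimen composition, metrics."""

import math

import numpy as np
import pytest

from pkchip import datasets
from pkchip.pk import ConcentrationSeries
from pkchip.schedule import (
    ExposureSchedule,
    PiecewiseTimeline,
    ReservoirStep,
    build_exposure_schedule,
    compose_treatment_timeline,
    equal_auc_boundaries,
    exposure_metrics,
    interval_mean_concentration,
    mimic_schedule_from_series,
    parse_pump_program,
    regimen_from_token,
    serialize_schedule,
)


def constant_series(value=7.0, t0=0.0, t1=24.0, n=25):
    t = np.linspace(t0, t1, n)
    return ConcentrationSeries("const", t, np.full(n, value), "simulated")


class TestIntervalMean:
    def test_constant_profile(self):
        assert interval_mean_concentration(constant_series(7.0), 2.0, 9.5) == pytest.approx(7.0)

    def test_linear_decay_symmetry(self):
        series = ConcentrationSeries("lin", [0.0, 10.0], [10.0, 0.0])
        assert interval_mean_concentration(series, 0.0, 10.0) == pytest.approx(5.0)

    def test_matches_fine_grid_riemann_sum_on_bundled_profile(self, sn38_series):
        t0, t1 = 1.0, 2.0
        mean = interval_mean_concentration(sn38_series, t0, t1)
        grid = np.arange(t0, t1 + 1e-12, 0.001)
        oracle = np.trapezoid(sn38_series.interp(grid), grid) / (t1 - t0)
        assert mean == pytest.approx(oracle, rel=1e-6)
        window = sn38_series.concentrations[
            (sn38_series.times >= t0) & (sn38_series.times <= t1)
        ]
        assert window.min() <= mean <= window.max()

    def test_rejects_interval_outside_support(self, sn38_series):
        with pytest.raises(ValueError, match="support"):
            interval_mean_concentration(sn38_series, 0.0, 2.0)


class TestEqualAucBoundaries:
    def test_constant_profile_gives_uniform_partition(self):
        b = equal_auc_boundaries(constant_series(), 4)
        np.testing.assert_allclose(b, [0.0, 6.0, 12.0, 18.0, 24.0], atol=1e-9)

    def test_single_step_returns_support(self, sn38_series):
        np.testing.assert_allclose(equal_auc_boundaries(sn38_series, 1), [1.0, 24.0])

    def test_exponential_decay_matches_analytic_quantiles(self, exponential_series):
        ke, horizon = 0.2, 24.0
        b = equal_auc_boundaries(exponential_series, 4)
        total = 1.0 - math.exp(-ke * horizon)
        analytic = [-math.log(1.0 - q * total) / ke for q in (0.25, 0.5, 0.75)]
        np.testing.assert_allclose(b[1:-1], analytic, atol=0.02)

    def test_rejects_zero_auc(self):
        zero = ConcentrationSeries("z", [0.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="zero AUC"):
            equal_auc_boundaries(zero, 4)


class TestBuildSchedule:
    def test_constant_profile_is_represented_exactly(self):
        series = constant_series(10.0)
        sched = build_exposure_schedule(series, [0.0, 6.0, 12.0, 24.0])
        assert [s.concentrations["const"] for s in sched.steps] == [10.0] * 3
        m = exposure_metrics(sched.timeline("const"), reference=series)
        assert m.mismatch == pytest.approx(0.0, abs=1e-9)

    def test_mimicry_reproduces_published_cmax_values(self, sn38_series, azd_series):
        sched = mimic_schedule_from_series({"SN38": sn38_series, "AZD0156": azd_series})
        assert len(sched.steps) == 8
        assert sched.max_concentration("SN38") == pytest.approx(5.5)
        assert sched.max_concentration("AZD0156") == pytest.approx(192.0)

    def test_equal_auc_schedule_preserves_reference_auc(self, exponential_series):
        b = equal_auc_boundaries(exponential_series, 8)
        sched = build_exposure_schedule(exponential_series, b)
        auc_ref = exposure_metrics(exponential_series).auc
        auc_sched = exposure_metrics(sched.timeline("exp")).auc
        assert auc_sched == pytest.approx(auc_ref, rel=0.01)

    def test_step_concentrations_bounded_by_profile_range(self, sn38_series):
        b = equal_auc_boundaries(sn38_series, 8)
        sched = build_exposure_schedule(sn38_series, b, sig_figs=12)
        for step, lo, hi in zip(sched.steps, b[:-1], b[1:]):
            window = sn38_series.interp(np.linspace(lo, hi, 50))
            c = step.concentrations["SN38"]
            assert window.min() - 1e-9 <= c <= window.max() + 1e-9

    def test_mismatch_non_increasing_with_step_count(self, exponential_series):
        mism = []
        for n in range(1, 17):
            b = equal_auc_boundaries(exponential_series, n)
            sched = build_exposure_schedule(exponential_series, b, sig_figs=12)
            mism.append(
                exposure_metrics(sched.timeline("exp"), reference=exponential_series).mismatch
            )
        assert all(b <= a + 1e-9 for a, b in zip(mism, mism[1:]))

    def test_rejects_mismatched_supports(self, sn38_series):
        other = constant_series(1.0, t0=0.0, t1=24.0)
        with pytest.raises(ValueError, match="support"):
            build_exposure_schedule({"a": sn38_series, "b": other}, [1.0, 24.0])


class TestScheduleInvariants:
    def test_durations_must_sum_to_cycle_length(self):
        steps = [
            ReservoirStep(1, {"d": 1.0}, 0.0, 12.0),
            ReservoirStep(2, {"d": 2.0}, 12.0, 6.0),
        ]
        with pytest.raises(ValueError, match="cycle_length"):
            ExposureSchedule(steps=steps, cycle_length=24.0)

    def test_steps_must_be_contiguous(self):
        steps = [
            ReservoirStep(1, {"d": 1.0}, 0.0, 6.0),
            ReservoirStep(2, {"d": 2.0}, 10.0, 14.0),
        ]
        with pytest.raises(ValueError, match="contiguous"):
            ExposureSchedule(steps=steps, cycle_length=24.0)


@pytest.fixture(scope="module")
def published():
    return datasets.published_reservoir_schedule()


class TestComposeTimeline:
    def test_monotherapy_doses_only_day_one(self, published):
        tl = compose_treatment_timeline(
            regimen_from_token("mono"), {"SN38": published, "AZD0156": published}
        )
        t = np.linspace(0.0, 167.9, 1000)
        sn = tl["SN38"].conc_at(t)
        assert np.all(sn[t < 24.0] > 0.0)
        assert np.all(sn[t >= 24.0] == 0.0)
        assert np.all(tl["AZD0156"].conc_at(t) == 0.0)

    def test_full_week_combination_covers_every_day(self, published):
        tl = compose_treatment_timeline(
            regimen_from_token("combo_7_7"), {"SN38": published, "AZD0156": published}
        )
        t = np.linspace(0.0, 167.9, 2000)
        assert np.all(tl["AZD0156"].conc_at(t) > 0.0)

    @pytest.mark.parametrize(
        "token,days", [("combo_gap24", {2, 3, 4}), ("combo_gap72", {4, 5, 6})]
    )
    def test_gap_regimens_place_atmi_on_the_stated_days(self, published, token, days):
        tl = compose_treatment_timeline(
            regimen_from_token(token), {"SN38": published, "AZD0156": published}
        )
        for day in range(1, 8):
            t = np.linspace((day - 1) * 24.0, day * 24.0 - 0.1, 200)
            dosed = np.any(tl["AZD0156"].conc_at(t) > 0.0)
            assert dosed == (day in days)

    def test_empty_dosing_days_give_zero_timeline(self, published):
        tl = compose_treatment_timeline(
            regimen_from_token("control"), {"SN38": published, "AZD0156": published}
        )
        t = np.linspace(0.0, 167.0, 500)
        assert np.all(tl["SN38"].conc_at(t) == 0.0)

    def test_unknown_token_is_rejected(self):
        with pytest.raises(ValueError, match="unknown regimen token"):
            regimen_from_token("weekly")


class TestExposureMetrics:
    def test_static_six_day_exposure_auc(self):
        tl = PiecewiseTimeline(np.array([0.0, 144.0]), np.array([5.5]))
        m = exposure_metrics(tl)
        assert m.auc == pytest.approx(5.5 * 144.0)
        assert m.cmax == pytest.approx(5.5)

    def test_mismatch_of_profile_with_itself_is_zero(self, sn38_series):
        m = exposure_metrics(sn38_series, reference=sn38_series)
        assert m.mismatch == pytest.approx(0.0, abs=1e-9)

    def test_tmax_earliest_on_ties(self):
        series = ConcentrationSeries("x", [0.0, 1.0, 2.0, 3.0], [1.0, 5.0, 5.0, 2.0])
        assert exposure_metrics(series).tmax == 1.0

    def test_time_above_threshold_by_interpolation(self):
        series = ConcentrationSeries("x", [0.0, 10.0], [10.0, 0.0])
        m = exposure_metrics(series, thresholds=[5.0])
        assert m.time_above[5.0] == pytest.approx(5.0)
        with pytest.raises(ValueError, match="threshold"):
            exposure_metrics(series, thresholds=[-1.0])


@pytest.fixture(scope="module")
def mono_program(published):
    # drop AZD concentrations: SN38-only reservoirs for a monotherapy run
    sn_only = ExposureSchedule(
        steps=[
            ReservoirStep(s.index, {"SN38": s.concentrations["SN38"]}, s.start_time, s.duration)
            for s in published.steps
        ],
        cycle_length=published.cycle_length,
        flow_rate=published.flow_rate,
    )
    return serialize_schedule(sn_only, regimen_from_token("mono"))


class TestPumpProgram:
    def test_record_count_matches_steps_times_dosing_days(self, sn38_series, azd_series):
        sched = mimic_schedule_from_series({"SN38": sn38_series, "AZD0156": azd_series})
        text = serialize_schedule(sched, regimen_from_token("mono"))
        records = parse_pump_program(text)
        assert len([r for r in records if r["analyte"] == "SN38"]) == 8

    def test_round_trip(self, mono_program):
        records = parse_pump_program(mono_program)
        rebuilt = [
            f"{r['day']},{r['reservoir']},{r['start_h']:g},{r['duration_h']:g},"
            f"{r['analyte']},{r['conc_nM']:g},{r['flow_uL_min']:g}"
            for r in records
        ]
        assert mono_program.splitlines()[1:] == rebuilt

    def test_default_flow_rate_is_twenty(self, mono_program):
        assert all(r["flow_uL_min"] == 20.0 for r in parse_pump_program(mono_program))

    def test_malformed_record_names_the_line(self, mono_program):
        broken = mono_program.splitlines()
        broken[3] = "1,2,three,4,SN38,5,20"
        with pytest.raises(ValueError, match="line 4"):
            parse_pump_program("\n".join(broken))
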