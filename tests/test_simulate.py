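import math

import numpy as np
import pytest

from respirotools import (
    ChamberSpec,
    CycleSchedule,
    FishPhysiology,
    FishRecord,
    Protocol,
    SensorModel,
    mmr_postexercise,
    mmr_swim,
    process_trace,
    simulate_chase_trial,
    simulate_circle_trial,
    simulate_cohort,
    simulate_swim_trial,
    ucrit,
    UcritInputs,
)


def _measure_windows(truth):
    return [w for w in truth.windows if w["phase"] == "measure"]


class TestSwimTrial:
    def test_constant_uptake_gives_exact_lines(self, fish, swim_chamber, noise_free):
        # c is irrelevant when the fish never exceeds one speed: check the
        # first measured window is an exact straight line of slope -m*M/V
        phys = FishPhysiology(170.0, 1300.0, 10.3, activity_sigma=0.0)
        tr, truth = simulate_swim_trial(fish, phys, swim_chamber,
                                        sensor=noise_free, seed=0)
        w = _measure_windows(truth)[0]
        sl = tr.window_slice(w["start"], w["end"])
        t, y = tr.time_s[sl], tr.o2_mg_l[sl]
        expected = -w["mean_m"] * fish.mass_kg / (3600 * swim_chamber.v_resp_l(fish))
        slopes = np.diff(y) / np.diff(t)
        np.testing.assert_allclose(slopes, expected, rtol=1e-9)

    def test_thirteen_completed_speeds_then_failure(self, fish, quiet_phys,
                                                    swim_chamber, noise_free):
        tr, truth = simulate_swim_trial(fish, quiet_phys, swim_chamber,
                                        sensor=noise_free, seed=0)
        # ucrit 10.3: speeds 4.0..10.0 completed (13), failure during 10.5
        assert truth.last_completed_speed_bl_s == 10.0
        assert truth.failed_speed_bl_s == 10.5
        full = [s for s, n in truth.completed_cycles.items() if n == 3]
        assert len(full) == 13
        # Brett's interpolation on the recorded fatigue time recovers Ucrit
        rec = ucrit(UcritInputs(10.0, 0.5, truth.fatigue_time_s, 1440.0))
        assert rec == pytest.approx(10.3, abs=1e-9)

    def test_same_seed_identical_different_seed_differs(self, fish, phys,
                                                        swim_chamber):
        tr1, _ = simulate_swim_trial(fish, phys, swim_chamber, seed=5)
        tr2, _ = simulate_swim_trial(fish, phys, swim_chamber, seed=5)
        tr3, _ = simulate_swim_trial(fish, phys, swim_chamber, seed=6)
        np.testing.assert_array_equal(tr1.o2_mg_l, tr2.o2_mg_l)
        assert not np.array_equal(tr1.o2_mg_l, tr3.o2_mg_l)

    def test_ucrit_below_start_speed_rejected(self, fish, swim_chamber):
        phys = FishPhysiology(170.0, 1300.0, 3.0)
        with pytest.raises(ValueError, match="start speed"):
            simulate_swim_trial(fish, phys, swim_chamber)


class TestChaseTrial:
    def test_attenuation_one_infinite_tau_first_window_is_mmr(
            self, fish, rest_chamber, noise_free):
        phys = FishPhysiology(170.0, 1300.0, 10.3, epoc_tau_s=float("inf"),
                              activity_sigma=0.0,
                              method_attenuation={"chase": 1.0})
        tr, truth = simulate_chase_trial(fish, phys, rest_chamber,
                                         sensor=noise_free, seed=0,
                                         duration_s=4800)
        series = process_trace(tr, fish, rest_chamber)
        assert series.entries[0].mo2 == pytest.approx(1300.0, rel=1e-9)

    def test_peak_excess_matches_window_mean_closed_form(
            self, fish, rest_chamber, noise_free):
        tau, delay, att = 900.0, 0.0, 0.8
        phys = FishPhysiology(170.0, 1300.0, 10.3, epoc_tau_s=tau,
                              activity_sigma=0.0,
                              method_attenuation={"chase": att})
        tr, truth = simulate_chase_trial(fish, phys, rest_chamber,
                                         sensor=noise_free, delay_s=delay,
                                         seed=0, duration_s=4800)
        est = mmr_postexercise(tr, Protocol.CHASE, fish, rest_chamber)
        # steepest 1-min window starts at t=0; its mean excess is
        # A * tau/60 * (1 - exp(-60/tau))
        expected = att * 1130.0 * tau / 60.0 * (1 - math.exp(-60.0 / tau))
        # OLS slope of the integrated-exponential decline sits within
        # window-averaging error of the analytic window mean
        assert est.value - 170.0 == pytest.approx(expected, rel=5e-3)
        assert (est.value - 170.0) / 1130.0 == pytest.approx(att, rel=0.05)

    def test_handling_delay_lowers_peak(self, fish, rest_chamber, noise_free):
        kw = dict(smr_true=170.0, mmr_true=1300.0, ucrit_true_bl_s=10.3,
                  epoc_tau_s=120.0, activity_sigma=0.0)
        phys = FishPhysiology(**kw)
        vals = []
        for delay in (0.0, 10.0):
            tr, _ = simulate_chase_trial(fish, phys, rest_chamber,
                                         sensor=noise_free, delay_s=delay,
                                         seed=0, duration_s=4800)
            vals.append(mmr_postexercise(tr, Protocol.CHASE, fish,
                                         rest_chamber).value)
        assert vals[1] < vals[0]

    def test_late_windows_settle_to_smr(self, fish, rest_chamber, noise_free):
        phys = FishPhysiology(170.0, 1300.0, 10.3, activity_sigma=0.0)
        tr, truth = simulate_chase_trial(fish, phys, rest_chamber,
                                         sensor=noise_free, seed=0)
        series = process_trace(tr, fish, rest_chamber)
        late = [e.mo2 for e in series.entries if e.window[0] >= 6 * 3600]
        assert np.allclose(late, 170.0, rtol=1e-3)


class TestCircleTrial:
    def test_plateau_recovered_after_ramp(self, fish, circle_chamber, noise_free):
        phys = FishPhysiology(170.0, 1300.0, 10.3, activity_sigma=0.0,
                              method_attenuation={"circle": 0.77})
        tr, truth = simulate_circle_trial(fish, phys, circle_chamber,
                                          sensor=noise_free, exercise_s=360,
                                          seed=0, duration_s=4800)
        est = mmr_postexercise(tr, Protocol.CIRCLE, fish, circle_chamber)
        plateau = 170.0 + 0.77 * 1130.0
        assert est.value == pytest.approx(plateau, rel=1e-6)
        assert est.window[0] >= 60.0  # after the ramp

    def test_attenuation_ordering_preserved(self, fish, circle_chamber,
                                            rest_chamber, noise_free):
        phys = FishPhysiology(170.0, 1300.0, 10.3, activity_sigma=0.0,
                              method_attenuation={"chase": 0.85, "circle": 0.70})
        tr_ch, _ = simulate_chase_trial(fish, phys, rest_chamber,
                                        sensor=noise_free, seed=0,
                                        duration_s=4800)
        tr_ci, _ = simulate_circle_trial(fish, phys, circle_chamber,
                                         sensor=noise_free, seed=0,
                                         duration_s=4800)
        mmr_ch = mmr_postexercise(tr_ch, Protocol.CHASE, fish, rest_chamber).value
        mmr_ci = mmr_postexercise(tr_ci, Protocol.CIRCLE, fish, circle_chamber).value
        assert mmr_ci < mmr_ch

    def test_reproducible_under_seed(self, fish, phys, circle_chamber):
        tr1, _ = simulate_circle_trial(fish, phys, circle_chamber, seed=3)
        tr2, _ = simulate_circle_trial(fish, phys, circle_chamber, seed=3)
        np.testing.assert_array_equal(tr1.o2_mg_l, tr2.o2_mg_l)

    def test_exercise_duration_bounds(self, fish, phys, circle_chamber):
        with pytest.raises(ValueError, match="exercise_s"):
            simulate_circle_trial(fish, phys, circle_chamber, exercise_s=200)


class TestMassBalanceAndFlush:
    def test_mass_balance_exact_with_background(self, fish, rest_chamber):
        sensor = SensorModel(noise_sd=0.0, background_rate_0=0.05,
                             background_slope=0.01)
        phys = FishPhysiology(170.0, 1300.0, 10.3, activity_sigma=0.0)
        tr, truth = simulate_chase_trial(fish, phys, rest_chamber,
                                         sensor=sensor, seed=0, duration_s=4800)
        v = rest_chamber.v_resp_l(fish)
        for w in truth.windows:
            t0, t1 = w["start"], w["end"]
            m_int = w["mean_m"] * (t1 - t0) * fish.mass_kg
            b_int = 0.05 * (t1 - t0) + 0.01 * (t1**2 - t0**2) / 7200.0
            expected_drop = (m_int + b_int) / (3600.0 * v)
            assert tr.sat_conc_mg_l - w["o2_min_clean"] == pytest.approx(
                expected_drop, rel=1e-9)

    def test_instant_flush_restores_saturation_exactly(self, fish, rest_chamber,
                                                       noise_free, phys):
        tr, truth = simulate_chase_trial(fish, phys, rest_chamber,
                                         sensor=noise_free, seed=0,
                                         duration_s=4800)
        # first sample of every cycle after the first starts at saturation
        cycle = 480.0
        starts = np.arange(cycle, tr.time_s[-1], cycle)
        idx = np.searchsorted(tr.time_s, starts)
        np.testing.assert_allclose(tr.o2_mg_l[idx], tr.sat_conc_mg_l, rtol=1e-12)

    def test_exponential_flush_monotone_approach(self, fish, rest_chamber, phys):
        sensor = SensorModel(noise_sd=0.0, flush_mode="exponential",
                             flush_rate_per_s=0.03)
        tr, _ = simulate_chase_trial(fish, phys, rest_chamber, sensor=sensor,
                                     seed=0, duration_s=4800)
        sl = tr.window_slice(300.0, 480.0)  # first flush
        flush = tr.o2_mg_l[sl]
        assert np.all(np.diff(flush) > 0)
        assert np.all(flush < tr.sat_conc_mg_l)

    def test_saturation_floor_flagged_not_fatal(self, rest_chamber, noise_free):
        big = FishRecord("big", "s", "BCF", 0.04, 0.12)  # 40 g in 1.6 L
        phys = FishPhysiology(250.0, 1400.0, 10.3, activity_sigma=0.0)
        tr, _ = simulate_chase_trial(big, phys, rest_chamber,
                                     sensor=noise_free, seed=0, duration_s=4800)
        assert any("80%" in w for w in tr.warnings)


class TestCohort:
    def test_zero_sd_design_gives_identical_fish(self):
        from respirotools import SpeciesDesign
        design = [SpeciesDesign("sp", "BCF", 2, 0.015, 0.0, 0.08, 0.0,
                                170.0, 0.0, 1300.0, 0.0, 10.3, 0.0)]
        _, meta, truths, reg = simulate_cohort(
            design, seed=0, chase_duration_s=4800, circle_duration_s=4800)
        p0 = reg[meta.fish_id.iloc[0]][1]
        p1 = reg[meta.fish_id.iloc[1]][1]
        assert p0.smr_true == p1.smr_true == 170.0
        assert p0.mmr_true == p1.mmr_true == 1300.0

    def test_masked_trial_absent_but_pipeline_runs(self):
        from respirotools import SpeciesDesign
        design = [SpeciesDesign("sp", "BCF", 2, 0.015, 0.1, 0.08, 0.05,
                                170.0, 0.1, 1300.0, 0.1, 10.3, 0.05)]
        traces, meta, truths, reg = simulate_cohort(
            design, seed=1, chase_duration_s=4800, circle_duration_s=4800,
            mask={"s_00": [Protocol.CIRCLE]})
        assert ("s_00", Protocol.CIRCLE) not in traces
        assert ("s_00", Protocol.SWIM) in traces
        assert ("s_01", Protocol.CIRCLE) in traces

    def test_cohort_mean_mmr_ordering_swim_chase_circle(self):
        """With attenuations 1 >= a_chase >= a_circle the recovered cohort
        means preserve the protocol ordering."""
        from respirotools import SpeciesDesign, smr_lowest_fraction
        design = [SpeciesDesign("sp", "BCF", 10, 0.015, 0.15, 0.08, 0.05,
                                170.0, 0.2, 1300.0, 0.2, 10.3, 0.1)]
        traces, meta, truths, reg = simulate_cohort(
            design, seed=2, chase_duration_s=4800, circle_duration_s=4800)
        means = {}
        for proto in (Protocol.SWIM, Protocol.CHASE, Protocol.CIRCLE):
            vals = []
            for fid in meta.fish_id:
                fish, _ = reg[fid]
                tr = traces[(fid, proto)]
                ch = ChamberSpec.default(
                    Protocol.REST if proto == Protocol.CHASE else proto)
                if proto == Protocol.SWIM:
                    series = process_trace(tr, fish, ch)
                    truth = truths[(fid, proto)]
                    vals.append(mmr_swim(series, truth.speed_by_window,
                                         truth.completed_cycles).value)
                else:
                    vals.append(mmr_postexercise(tr, proto, fish, ch).value)
            means[proto] = np.mean(vals)
        assert means[Protocol.SWIM] > means[Protocol.CHASE] > means[Protocol.CIRCLE]

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError, match="n_per_species"):
            simulate_cohort(n_per_species=0, seed=0)
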