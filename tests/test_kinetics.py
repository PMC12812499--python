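import numpy as np
import pytest

from hdkinetics import (ConvergenceError, DialysisSession, SoluteParameters,
                        WEEK_MINUTES, WeekIntegrator, WeeklySchedule,
                        creatinine_parameters, predialysis_value,
                        postdialysis_value, simulate_week,
                        time_averaged_water_concentration, what_if_predict)
from hdkinetics.kinetics import WeeklyProfile
from oracles import euler_week_1s


def constant_profile(value, n=WEEK_MINUTES, vd=22.7):
    arr = np.full(n, value)
    return WeeklyProfile(C1=arr, C2=arr.copy(), V_total=np.full(n, vd),
                         converged=True, weeks_to_converge=1)


class TestScheduleValidation:
    def test_overlapping_sessions_rejected(self):
        mk = lambda start: DialysisSession(day_index=0,
                                           start_minute_of_day=start,
                                           duration=240, Qb=300, Qd=500,
                                           k0a_invitro_urea=950, uf_volume=1.0)
        with pytest.raises(ValueError, match="overlap"):
            WeeklySchedule([mk(480), mk(600)])

    def test_sessions_sorted_by_start(self, sched2):
        starts = [s.start_minute for s in sched2.sessions]
        assert starts == sorted(starts)

    def test_interdialytic_window_wraps_week(self, sched2):
        start, end = sched2.interdialytic_window(0)
        # Friday session end -> next Monday start, crossing the boundary
        assert start == sched2.sessions[1].end_minute
        assert end == sched2.sessions[0].start_minute + WEEK_MINUTES


class TestClosedForms:
    def test_no_dialysis_steady_state_is_g_over_clearance(self, ref_patient):
        params = SoluteParameters("creatinine", G=1.0, Vd=22.7, Kr_water=10.0)
        profile = simulate_week(WeeklySchedule([]), params, ref_patient)
        assert profile.C1 == pytest.approx(np.full(WEEK_MINUTES, 0.1),
                                           rel=1e-5)
        # the distal pool sits G/Kc above, driving the generation flux
        kc = params.Kc_per_kg * ref_patient.weight_postdialysis
        assert profile.C2 == pytest.approx(
            np.full(WEEK_MINUTES, 0.1 + params.G / kc), rel=1e-5)

    def test_steady_state_splits_between_kr_and_ke(self, ref_patient):
        params = SoluteParameters("creatinine", G=1.0, Vd=22.7, Kr_water=6.0,
                                  Ke_water=4.0)
        profile = simulate_week(WeeklySchedule([]), params, ref_patient)
        assert profile.C1.mean() == pytest.approx(0.1, rel=1e-5)

    def test_open_loop_accumulation_without_clearance(self, ref_patient):
        params = SoluteParameters("creatinine", G=0.5, Vd=20.0)
        integ = WeekIntegrator(WeeklySchedule([]), params, ref_patient)
        m1, m2 = integ.run_week((0.0, 0.0), record=True)
        c_total = (m1 + m2) / (params.Vd * 1000.0)
        minutes = np.arange(WEEK_MINUTES + 1)
        expected = params.G * minutes / (params.Vd * 1000.0)
        assert c_total == pytest.approx(expected, abs=1e-12)

    def test_generation_without_any_clearance_never_converges(self, ref_patient):
        params = SoluteParameters("creatinine", G=1.0, Vd=20.0)
        with pytest.raises(ConvergenceError):
            simulate_week(WeeklySchedule([]), params, ref_patient)

    def test_single_pool_limit_matches_variable_volume_decay(self, ref_patient):
        """With enormous intercompartmental clearance the two pools fuse and
        the intradialytic decay follows the one-pool variable-volume power
        law C = C0 (V/V0)^(K/Quf - 1)."""
        session = DialysisSession(day_index=0, start_minute_of_day=0,
                                  duration=240, Qb=300, Qd=500,
                                  k0a_invitro_urea=950, uf_volume=2.0)
        sched = WeeklySchedule([session])
        params = SoluteParameters("creatinine", G=0.0, Vd=24.5,
                                  Kr_water=0.0, Ke_water=0.0, Kc_per_kg=1e5)
        integ = WeekIntegrator(sched, params, ref_patient)
        v0 = integ.V[0]
        c0 = 0.08
        f = params.proximal_fraction
        m1, m2 = integ.run_week((c0 * f * v0, c0 * (1 - f) * v0), record=True)
        k = integ.clearance[0]
        quf = session.uf_rate
        v_end = integ.V[240]
        c_model = m1[240] / (f * v_end)
        c_closed = c0 * (v_end / v0) ** (k / quf - 1.0)
        assert c_model == pytest.approx(c_closed, rel=0.01)


class TestSteadyStateInvariants:
    def test_periodicity(self, cohort_mean_case):
        _, profile = cohort_mean_case
        assert profile.converged
        assert profile.periodicity_gap < 1e-6

    def test_weekly_fluid_balance_closes(self, cohort_mean_case, ref_patient,
                                         sched2):
        params, _ = cohort_mean_case
        integ = WeekIntegrator(sched2, params, ref_patient)
        assert integ.V[0] == pytest.approx(integ.V[-1], rel=1e-9)
        for s in sched2.sessions:  # each session drains exactly its UF
            drop = integ.V[s.start_minute] - integ.V[s.end_minute]
            assert drop == pytest.approx(s.uf_volume * 1000.0, rel=1e-9)

    def test_weekly_mass_balance(self, cohort_mean_case, ref_patient, sched2):
        params, profile = cohort_mean_case
        integ = WeekIntegrator(sched2, params, ref_patient)
        c1 = np.append(profile.C1, profile.C1[0])
        per_minute = integ.clearance * (c1[:-1] + c1[1:]) / 2.0
        removed = float(per_minute.sum())
        assert removed == pytest.approx(params.G * WEEK_MINUTES, rel=1e-3)

    def test_removal_split_sums_to_generation(self, cohort_mean_case):
        params, profile = cohort_mean_case
        total = (profile.removal_dialyzer_mg + profile.removal_kidney_mg
                 + profile.removal_extrarenal_mg)
        assert total == pytest.approx(params.G * WEEK_MINUTES, rel=1e-6)

    def test_predialysis_in_clinical_range_at_cohort_means(
            self, cohort_mean_case, sched2):
        _, profile = cohort_mean_case
        pre = predialysis_value(profile, sched2)
        assert 5.1 < pre < 9.7  # reported cohort range, mean +/- SD

    def test_predialysis_monotone_in_kr_and_g(self, ref_patient, sched2):
        pres = [what_if_predict(1200.0, 24.5, kr, sched2, ref_patient)[0]
                for kr in (0.0, 5.0, 10.0)]
        assert pres[0] > pres[1] > pres[2]
        low = what_if_predict(800.0, 24.5, 5.0, sched2, ref_patient)[0]
        high = what_if_predict(1600.0, 24.5, 5.0, sched2, ref_patient)[0]
        assert high > low


class TestSampling:
    def test_water_to_plasma_conversion_of_predialysis_sample(self, sched2):
        profile = constant_profile(0.1075)
        assert predialysis_value(profile, sched2) == pytest.approx(10.0,
                                                                   abs=0.005)

    def test_predialysis_is_weekly_maximum_on_once_weekly(self, ref_patient,
                                                          sched1):
        params = creatinine_parameters(1091.0, 22.7, 5.0, ref_patient)
        profile = simulate_week(sched1, params, ref_patient)
        start = sched1.sessions[0].start_minute
        assert int(np.argmax(profile.C1)) == start
        assert predialysis_value(profile, sched1) == pytest.approx(
            profile.C1.max() * profile.plasma_water_fraction * 100.0)

    def test_post_below_pre(self, cohort_mean_case, sched2):
        _, profile = cohort_mean_case
        assert postdialysis_value(profile, sched2) < \
            predialysis_value(profile, sched2)


class TestTimeAveragedConcentration:
    def test_constant_profile(self):
        profile = constant_profile(0.0926)
        assert time_averaged_water_concentration(profile, 100, 1540) == \
            pytest.approx(0.0926)

    def test_linear_ramp_gives_midpoint(self):
        profile = constant_profile(1.0)
        profile.C1[1000:2000] = np.linspace(0.05, 0.11, 1000)
        assert time_averaged_water_concentration(profile, 1000, 2000) == \
            pytest.approx(0.08, rel=1e-12)

    def test_wrapping_window(self):
        profile = constant_profile(1.0)
        profile.C1[:] = np.arange(WEEK_MINUTES)
        got = time_averaged_water_concentration(profile, WEEK_MINUTES - 10,
                                                WEEK_MINUTES + 10)
        expected = np.r_[np.arange(WEEK_MINUTES - 10, WEEK_MINUTES),
                         np.arange(10)].mean()
        assert got == pytest.approx(expected)

    def test_agrees_with_trapezoid_on_24h_predialysis_window(
            self, cohort_mean_case, sched2):
        _, profile = cohort_mean_case
        end = sched2.sessions[0].start_minute + WEEK_MINUTES
        start = end - 1440
        mean = time_averaged_water_concentration(profile, start, end)
        idx = np.arange(start, end + 1) % WEEK_MINUTES
        trap = np.trapezoid(profile.C1[idx]) / 1440.0
        assert mean == pytest.approx(trap, rel=1e-3)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            time_averaged_water_concentration(constant_profile(1.0), 50, 50)


class TestStepSizeRobustness:
    def test_minute_step_matches_one_second_euler(self, cohort_mean_case,
                                                  ref_patient, sched2):
        """Open-loop propagation over a full week from the converged state:
        the exact-exponential minute stepping stays within 0.5% of a
        brute-force 1-second Euler walk of the same equations."""
        params, profile = cohort_mean_case
        integ = WeekIntegrator(sched2, params, ref_patient)
        f = params.proximal_fraction
        v0 = integ.V[0]
        x0 = (profile.C1[0] * f * v0, profile.C2[0] * (1 - f) * v0)
        m1_fast, _ = integ.run_week(x0, record=True)
        m1_oracle, _ = euler_week_1s(integ, x0)
        rel = np.abs(m1_fast - m1_oracle) / m1_oracle
        assert rel.max() < 5e-3
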