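import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hdkinetics import (UrineCollection, WEEK_MINUTES,
                        compare_collection_modes, creatinine_parameters,
                        excretion_rate, krcrw_from_urine, simulate_week)
from hdkinetics.kinetics import WeeklyProfile


def flat_profile(value):
    arr = np.full(WEEK_MINUTES, value)
    return WeeklyProfile(C1=arr, C2=arr.copy(),
                         V_total=np.full(WEEK_MINUTES, 22.7),
                         converged=True, weeks_to_converge=1)


class TestExcretionRate:
    def test_reference_value(self):
        c = UrineCollection(start_minute=0, end_minute=1440, volume=1000.0,
                            creatinine_conc=100.0)  # 1000 mg over 24 h
        assert excretion_rate(c) == pytest.approx(0.6944, abs=1e-4)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(vol=st.floats(100, 3000), conc=st.floats(10, 300),
           minutes=st.integers(240, 2500), scale=st.floats(1.1, 4))
    def test_scale_invariance(self, vol, conc, minutes, scale):
        a = UrineCollection(0, minutes, vol, conc)
        b = UrineCollection(0, int(minutes * scale) + 1,
                            vol * ((int(minutes * scale) + 1) / minutes), conc)
        assert excretion_rate(a) == pytest.approx(excretion_rate(b), rel=1e-9)

    def test_pooled_rate_is_duration_weighted_mean_of_aliquots(self):
        a1 = UrineCollection(0, 1000, 600.0, 120.0)
        a2 = UrineCollection(1000, 2440, 900.0, 80.0)
        pooled = UrineCollection(
            0, 2440, a1.volume + a2.volume,
            (a1.creatinine_mass + a2.creatinine_mass)
            / (a1.volume + a2.volume) * 100.0,
            aliquots=(a1, a2))
        weighted = (excretion_rate(a1) * 1000 + excretion_rate(a2) * 1440) / 2440
        assert excretion_rate(pooled) == pytest.approx(weighted, rel=1e-12)

    def test_aliquots_must_tile(self):
        with pytest.raises(ValueError, match="tile|span"):
            UrineCollection(0, 2000, 100.0, 50.0,
                            aliquots=(UrineCollection(0, 900, 50.0, 50.0),
                                      UrineCollection(1000, 2000, 50.0, 50.0)))


class TestKrcrwFromUrine:
    def test_reference_arithmetic(self):
        c = UrineCollection(0, 1440, 1000.0, 100.0)  # 0.6944 mg/min
        profile = flat_profile(0.0926)
        assert krcrw_from_urine(c, profile) == pytest.approx(7.50, abs=0.01)

    def test_linear_in_urine_concentration(self):
        profile = flat_profile(0.08)
        c1 = UrineCollection(0, 1440, 800.0, 60.0)
        c2 = UrineCollection(0, 1440, 800.0, 120.0)
        assert krcrw_from_urine(c2, profile) == \
            pytest.approx(2 * krcrw_from_urine(c1, profile), rel=1e-12)

    def test_invariant_to_aliquot_split_and_recombination(self):
        profile = flat_profile(0.09)
        a1 = UrineCollection(100, 1540, 700.0, 90.0)
        a2 = UrineCollection(1540, 2980, 500.0, 110.0)
        mass = a1.creatinine_mass + a2.creatinine_mass
        vol = a1.volume + a2.volume
        pooled = UrineCollection(100, 2980, vol, mass / vol * 100.0,
                                 aliquots=(a1, a2))
        direct = UrineCollection(100, 2980, vol, mass / vol * 100.0)
        assert krcrw_from_urine(pooled, profile) == \
            pytest.approx(krcrw_from_urine(direct, profile), rel=1e-12)

    def test_self_consistency_on_simulated_patient(self, ref_patient, sched2):
        """Urine built from the model's own Kr x C1 integral returns the
        simulation's input clearance."""
        kr_true = 6.2
        params = creatinine_parameters(1100.0, 23.0, kr_true, ref_patient)
        profile = simulate_week(sched2, params, ref_patient)
        w0, w1 = sched2.interdialytic_window()
        idx = np.arange(w0, w1) % WEEK_MINUTES
        mass = kr_true * float(profile.C1[idx].sum())
        urine = UrineCollection(w0, w1, 1500.0, mass / 1500.0 * 100.0)
        assert krcrw_from_urine(urine, profile) == pytest.approx(kr_true,
                                                                 rel=5e-3)


class TestCollectionModes:
    def test_constant_excretion_modes_agree(self, ref_patient, sched2,
                                            cohort_mean_case):
        params, profile = cohort_mean_case
        kr = params.Kr_water
        w0, w1 = sched2.interdialytic_window()
        c1 = profile.C1

        def window_mass(s, e):
            return kr * float(c1[np.arange(s, e) % WEEK_MINUTES].sum())

        last24 = UrineCollection(w1 - 1440, w1, 700.0,
                                 window_mass(w1 - 1440, w1) / 7.0)
        pooled = UrineCollection(w0, w1, 2000.0,
                                 window_mass(w0, w1) / 20.0)
        a, b = compare_collection_modes(last24, pooled, profile)
        assert a == pytest.approx(b, rel=5e-3)
        assert a == pytest.approx(kr, rel=5e-3)

    def test_declining_diuresis_lowers_last24h_value(self, cohort_mean_case,
                                                     sched2):
        """A kidney whose output fades through the interval excretes less in
        the final 24 h than a steady one would: the last-24h clearance drops
        below the pooled estimate."""
        params, profile = cohort_mean_case
        w0, w1 = sched2.interdialytic_window()
        idx_all = np.arange(w0, w1) % WEEK_MINUTES
        idx_24 = np.arange(w1 - 1440, w1) % WEEK_MINUTES
        # fading clearance: linearly from kr to 0.5 kr across the window
        kr_t = params.Kr_water * np.linspace(1.0, 0.5, w1 - w0)
        mass_all = float((kr_t * profile.C1[idx_all]).sum())
        mass_24 = float((kr_t[-1440:] * profile.C1[idx_24]).sum())
        last24 = UrineCollection(w1 - 1440, w1, 600.0, mass_24 / 6.0)
        pooled = UrineCollection(w0, w1, 1800.0, mass_all / 18.0)
        a, b = compare_collection_modes(last24, pooled, profile)
        assert a < b

    def test_single_window_idempotent(self, cohort_mean_case):
        _, profile = cohort_mean_case
        c = UrineCollection(1000, 2440, 800.0, 90.0)
        a, b = compare_collection_modes(c, c, profile)
        assert a == b
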