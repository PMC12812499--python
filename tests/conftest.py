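import pytest

from hdkinetics import (creatinine_parameters, reference_patient,
                        reference_schedule, simulate_week)


@pytest.fixture(scope="session")
def ref_patient():
    """Nominal 70-kg male patient used throughout."""
    return reference_patient()


@pytest.fixture(scope="session")
def sched1():
    return reference_schedule(1)


@pytest.fixture(scope="session")
def sched2():
    return reference_schedule(2)


@pytest.fixture(scope="session")
def cohort_mean_case(ref_patient, sched2):
    """Steady-state profile at the study-cohort mean parameters
    (GCr 1091 mg/day, VdCr 22.7 L, KrCrW 7.43 mL/min, 2/week)."""
    params = creatinine_parameters(1091.0, 22.7, 7.43, ref_patient)
    profile = simulate_week(sched2, params, ref_patient)
    return params, profile
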