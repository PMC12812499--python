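"""Reference schedules and the forward–inverse validation grid.

The validation exercise: predict predialysis serum creatinine with the
what-if model over every combination of 1–7 sessions/week, GCr in
{500, 1200, 2000} mg/day and KrCrW in {0, 2.5, 5, 7.5, 10, 15, 20} mL/min,
feed each prediction back into the KrCrW solver with the same GCr/VdCr, and
compare recovered with input clearance (147 points).
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .anthropometry import PatientProfile, vdcr_anthropometric
from .kinetics import DialysisSession, WeeklySchedule
from .solvers import MeasuredSamples, solve_krcrw, what_if_predict

__all__ = ["GRID_GCR_MG_DAY", "GRID_KRCRW_ML_MIN", "SCHEDULE_DAYS",
           "reference_patient", "reference_schedule", "roundtrip_point",
           "roundtrip_grid"]

GRID_GCR_MG_DAY = (500.0, 1200.0, 2000.0)
GRID_KRCRW_ML_MIN = (0.0, 2.5, 5.0, 7.5, 10.0, 15.0, 20.0)

#: Treatment days (0 = Monday) for 1..7 sessions/week. The 1/wk and 2/wk
#: rows mirror the study cohorts (Monday; Monday-Friday); denser schedules
#: follow common clinical patterns.
SCHEDULE_DAYS = {
    1: (0,),
    2: (0, 4),
    3: (0, 2, 4),
    4: (0, 1, 3, 5),
    5: (0, 1, 2, 3, 4),
    6: (0, 1, 2, 3, 4, 5),
    7: (0, 1, 2, 3, 4, 5, 6),
}

_SESSION_START = 480  # 08:00
_SESSION_MIN = 240
_QB, _QD = 300.0, 500.0
_K0A_ONCE_WEEKLY = 800.0   # F60S-class dialyzer used by the 1/wk cohort
_K0A_TWICE_WEEKLY = 950.0  # L18-class dialyzer used by the 2/wk cohort
_UF_ONCE, _UF_TWICE = 0.78, 1.28  # cohort mean UF volumes, L


def reference_patient() -> PatientProfile:
    """The nominal 70-kg patient used for grid exercises."""
    return PatientProfile(sex="male", age=60, weight_postdialysis=70.0,
                          height=170.0)


def reference_schedule(n_per_week: int, *, k0a_invitro_urea: float | None = None,
                       uf_volume: float | None = None) -> WeeklySchedule:
    """Standard n-sessions/week schedule: 240 min at Qb 300 / Qd 500,
    starting 08:00 on the days of :data:`SCHEDULE_DAYS`."""
    if n_per_week not in SCHEDULE_DAYS:
        raise ValueError("n_per_week must be 1..7")
    if k0a_invitro_urea is None:
        k0a_invitro_urea = (_K0A_ONCE_WEEKLY if n_per_week == 1
                            else _K0A_TWICE_WEEKLY)
    if uf_volume is None:
        uf_volume = _UF_ONCE if n_per_week == 1 else _UF_TWICE
    sessions = [DialysisSession(day_index=d, start_minute_of_day=_SESSION_START,
                                duration=_SESSION_MIN, Qb=_QB, Qd=_QD,
                                k0a_invitro_urea=k0a_invitro_urea,
                                uf_volume=uf_volume)
                for d in SCHEDULE_DAYS[n_per_week]]
    return WeeklySchedule(sessions, modeled_session_index=0)


def roundtrip_point(n_per_week: int, gcr: float, krcrw: float,
                    vdcr: float | None = None,
                    patient: PatientProfile | None = None) -> dict:
    """One forward–inverse round trip; returns the input and recovered
    KrCrW plus the intermediate predialysis value."""
    patient = patient or reference_patient()
    vdcr = vdcr if vdcr is not None else vdcr_anthropometric(
        patient.weight_postdialysis)
    schedule = reference_schedule(n_per_week)
    pre, _post = what_if_predict(gcr, vdcr, krcrw, schedule, patient)
    res = solve_krcrw(gcr, vdcr, MeasuredSamples(pre_scr=pre), schedule, patient)
    return {"n_per_week": n_per_week, "GCr_mg_day": gcr, "VdCr_L": vdcr,
            "KrCrW_in": krcrw, "pre_scr_mg_dl": pre,
            "KrCrW_recovered": res.KrCrW,
            "abs_error": abs(res.KrCrW - krcrw)}


def roundtrip_grid(schedules: Iterable[int] = range(1, 8),
                   gcr_values: Iterable[float] = GRID_GCR_MG_DAY,
                   krcrw_values: Iterable[float] = GRID_KRCRW_ML_MIN,
                   vdcr: float | None = None,
                   patient: PatientProfile | None = None) -> pd.DataFrame:
    """Run the full round-trip grid; one row per combination."""
    rows = [roundtrip_point(n, g, k, vdcr=vdcr, patient=patient)
            for n in schedules for g in gcr_values for k in krcrw_values]
    return pd.DataFrame(rows)
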