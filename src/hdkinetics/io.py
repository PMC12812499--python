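"""JSON/CSV input and output.

Configs are plain JSON: a patient file, a schedule file, and an optional
urine file. Weekly profiles go to CSV with explicit units in the headers;
results serialize to JSON with clearances reported in both water and plasma
terms (the classic unit pitfall: kinetic models produce *water* clearances,
~7% smaller than conventional plasma clearances).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .anthropometry import PatientProfile, water_to_plasma_clearance
from .kinetics import (DialysisSession, WeeklySchedule, WeeklyProfile,
                       WEEK_MINUTES)
from .solvers import ModelingResult
from .urine import UrineCollection

__all__ = ["load_patient", "load_schedule", "load_urine", "dump_patient",
           "dump_schedule", "write_profile_csv", "result_to_dict",
           "write_result_json", "clock_to_week_minute"]

_DAY_NAMES = ["monday", "tuesday", "wednesday", "thursday", "friday",
              "saturday", "sunday"]


def clock_to_week_minute(day: str | int, hhmm: str) -> int:
    """Absolute week minute (Monday 00:00 = 0) from a day name/index and an
    ``HH:MM`` clock time."""
    if isinstance(day, str):
        try:
            day = _DAY_NAMES.index(day.strip().lower())
        except ValueError:
            raise ValueError(f"unknown day {day!r}") from None
    if not 0 <= day <= 6:
        raise ValueError("day index must be 0..6")
    hh, mm = hhmm.split(":")
    minute = int(hh) * 60 + int(mm)
    if not 0 <= minute < 1440:
        raise ValueError(f"bad clock time {hhmm!r}")
    return day * 1440 + minute


def load_patient(path: str | Path) -> PatientProfile:
    with open(path) as fh:
        data = json.load(fh)
    try:
        return PatientProfile(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid patient file {path}: {exc}") from exc


def dump_patient(patient: PatientProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(patient.__dict__, fh, indent=2)
        fh.write("\n")


def load_schedule(path: str | Path) -> WeeklySchedule:
    with open(path) as fh:
        data = json.load(fh)
    try:
        sessions = [DialysisSession(**s) for s in data["sessions"]]
        return WeeklySchedule(sessions,
                              modeled_session_index=data.get(
                                  "modeled_session_index", 0))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid schedule file {path}: {exc}") from exc


def dump_schedule(schedule: WeeklySchedule, path: str | Path) -> None:
    data = {"modeled_session_index": schedule.modeled_session_index,
            "sessions": [s.__dict__ for s in schedule.sessions]}
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")


def load_urine(path: str | Path) -> UrineCollection:
    """Read a urine collection; aliquots optional. Fields as in
    :class:`~hdkinetics.urine.UrineCollection` (volume mL, conc mg/dL)."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        aliquots = tuple(UrineCollection(**a) for a in data.pop("aliquots", ()))
        return UrineCollection(aliquots=aliquots, **data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid urine file {path}: {exc}") from exc


def write_profile_csv(profile: WeeklyProfile, path: str | Path) -> None:
    """Weekly profile as CSV: minute, water concentrations (mg/mL), plasma
    concentration (mg/dL), total volume (L)."""
    pw = profile.plasma_water_fraction
    df = pd.DataFrame({
        "minute": np.arange(WEEK_MINUTES),
        "C1_water_mg_ml": profile.C1,
        "C2_water_mg_ml": profile.C2,
        "C_plasma_mg_dl": profile.C1 * pw * 100.0,
        "V_total_L": profile.V_total,
    })
    df.to_csv(path, index=False, float_format="%.6g")


def result_to_dict(result: ModelingResult,
                   plasma_protein_fraction: float = 0.07) -> dict:
    """Serialize a :class:`ModelingResult` with explicit units, reporting the
    residual clearance both as water and as conventional plasma clearance."""
    return {
        "GCr_mg_day": result.GCr,
        "VdCr_L": result.VdCr,
        "KrCrW_water_ml_min": result.KrCrW,
        "KrCr_plasma_ml_min": water_to_plasma_clearance(
            result.KrCrW, plasma_protein_fraction),
        "predicted_pre_mg_dl": result.predicted_pre,
        "predicted_post_mg_dl": result.predicted_post,
        "tac_water_mg_ml": result.tac_water_window,
        "iterations": result.iterations,
        "converged": result.converged,
    }


def write_result_json(result: ModelingResult, path: str | Path, *,
                      plasma_protein_fraction: float = 0.07,
                      extra: dict | None = None) -> None:
    record = result_to_dict(result, plasma_protein_fraction)
    if extra:
        record.update(extra)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
        fh.write("\n")
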