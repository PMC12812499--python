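"""Inverse solvers and the forward "what-if" predictor.

Three modeling modes:

* :func:`what_if_predict` — given GCr, VdCr and KrCrW, predict the steady
  pre/post-dialysis plasma creatinine for a chosen session of the week.
* :func:`solve_krcrw` — the urine-free mode: given GCr, VdCr and one
  measured predialysis serum creatinine, find the residual kidney water
  clearance that reproduces it. The predialysis value is strictly
  decreasing in KrCrW, so a bracketed root find on [0, 40] mL/min is
  guaranteed.
* :func:`solve_generation` — the full modeling session: given measured
  pre and post serum creatinine plus a timed urine collection, fit GCr
  (outer loop, matching pre), VdCr (inner loop, matching the intradialytic
  drop) and the urine-based KrCrW (recomputed from the current profile's
  time-averaged concentration each pass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .anthropometry import PatientProfile
from .kinetics import (WeeklySchedule, creatinine_parameters,
                       predialysis_value, postdialysis_value, simulate_week,
                       time_averaged_water_concentration)
from .urine import UrineCollection, excretion_rate

__all__ = ["MeasuredSamples", "ModelingResult", "what_if_predict",
           "solve_krcrw", "solve_generation", "spktv",
           "KRCRW_BRACKET_MAX", "BracketError"]

#: Upper root bracket for residual clearance, mL/min — far above any
#: clearance compatible with needing dialysis.
KRCRW_BRACKET_MAX = 40.0

CONC_TOL_MG_DL = 1e-3       # match tolerance on plasma concentrations
CLEARANCE_TOL_ML_MIN = 0.01


class BracketError(RuntimeError):
    """Measured value lies outside the clearance bracket."""


@dataclass(frozen=True)
class MeasuredSamples:
    """Measured plasma creatinine around one session (mg/dL, plasma units —
    not water)."""

    pre_scr: float
    post_scr: float | None = None
    sample_session_index: int = 0

    def __post_init__(self) -> None:
        if self.pre_scr <= 0:
            raise ValueError("pre_scr must be positive")
        if self.post_scr is not None and not 0 < self.post_scr < self.pre_scr:
            raise ValueError("post_scr must lie in (0, pre_scr)")


@dataclass
class ModelingResult:
    """Fitted kinetic parameters with convergence diagnostics.

    GCr in mg/day, VdCr in L, KrCrW in mL/min of water (multiply by ~1.075
    for plasma clearance); predicted pre/post in plasma mg/dL;
    ``tac_water_window`` the time-averaged water concentration (mg/mL) over
    the urine window when one was used.
    """

    GCr: float
    VdCr: float
    KrCrW: float
    predicted_pre: float
    predicted_post: float | None
    tac_water_window: float | None
    iterations: int
    converged: bool


def what_if_predict(GCr: float, VdCr: float, KrCrW: float,
                    schedule: WeeklySchedule, patient: PatientProfile,
                    session_index: int | None = None,
                    ) -> tuple[float, float]:
    """Steady-state (pre, post) plasma creatinine, mg/dL, for one session.

    GCr in mg/day, VdCr in L, KrCrW in mL/min (water clearance).
    """
    params = creatinine_parameters(GCr, VdCr, KrCrW, patient)
    profile = simulate_week(schedule, params, patient)
    return (predialysis_value(profile, schedule, session_index),
            postdialysis_value(profile, schedule, session_index))


def _predicted_pre(GCr, VdCr, krcrw, schedule, patient, session_index):
    params = creatinine_parameters(GCr, VdCr, krcrw, patient)
    profile = simulate_week(schedule, params, patient)
    return predialysis_value(profile, schedule, session_index)


def solve_krcrw(GCr: float, VdCr: float, samples: MeasuredSamples,
                schedule: WeeklySchedule, patient: PatientProfile,
                *, bracket_max: float = KRCRW_BRACKET_MAX) -> ModelingResult:
    """Residual kidney creatinine water clearance from a single predialysis
    serum creatinine, without urine collection.

    The modeled predialysis value at fixed GCr/VdCr falls strictly as KrCrW
    rises, so the measured value pins a unique clearance, found by Brent's
    method on [0, ``bracket_max``] mL/min to 0.001 mg/dL in concentration.

    If the measured value exceeds even the anuric (KrCrW = 0) prediction the
    inputs are mutually inconsistent (GCr too low, VdCr off, or lab error):
    the result carries KrCrW = 0 with ``converged=False``. A measured value
    below the ``bracket_max`` prediction raises :class:`BracketError`.
    """
    if GCr <= 0 or VdCr <= 0:
        raise ValueError("GCr and VdCr must be positive")
    idx = samples.sample_session_index
    measured = samples.pre_scr
    evals = 0

    def f(kr):
        nonlocal evals
        evals += 1
        return _predicted_pre(GCr, VdCr, kr, schedule, patient, idx) - measured

    f0 = f(0.0)
    if f0 <= 0.0:  # anuric prediction at or below the measurement
        ok = abs(f0) <= CONC_TOL_MG_DL
        return ModelingResult(GCr=GCr, VdCr=VdCr, KrCrW=0.0,
                              predicted_pre=f0 + measured, predicted_post=None,
                              tac_water_window=None, iterations=evals,
                              converged=ok)
    fmax = f(bracket_max)
    if fmax > CONC_TOL_MG_DL:
        raise BracketError(
            f"measured predialysis creatinine {measured} mg/dL is below the "
            f"prediction at KrCrW = {bracket_max} mL/min; clearance above bracket")
    if fmax > 0.0:  # root effectively at the bracket edge
        kr = bracket_max
    else:
        kr = brentq(f, 0.0, bracket_max, xtol=1e-4)
    pre = _predicted_pre(GCr, VdCr, kr, schedule, patient, idx)
    evals += 1
    return ModelingResult(GCr=GCr, VdCr=VdCr, KrCrW=kr, predicted_pre=pre,
                          predicted_post=None, tac_water_window=None,
                          iterations=evals,
                          converged=abs(pre - measured) <= CONC_TOL_MG_DL)


def solve_generation(samples: MeasuredSamples, urine: UrineCollection,
                     schedule: WeeklySchedule, patient: PatientProfile,
                     *, max_outer: int = 100,
                     vd_bracket: tuple[float, float] = (3.0, 100.0),
                     ) -> ModelingResult:
    """Fit GCr, VdCr and the urine-based KrCrW from one modeling session.

    Iterates to the joint fixed point: VdCr is adjusted (inner bracketed
    root find) until the modeled post/pre ratio matches the measured one —
    the ratio is independent of GCr because the model is linear in
    generation — then GCr is rescaled in closed form to match the measured
    predialysis value, and KrCrW is refreshed from the urine excretion rate
    divided by the current profile's time-averaged water concentration.
    Converged when pre and post match within 0.001 mg/dL and KrCrW moves by
    less than 0.01 mL/min between passes.
    """
    if samples.post_scr is None:
        raise ValueError("solve_generation requires a postdialysis sample")
    idx = samples.sample_session_index
    target_ratio = samples.post_scr / samples.pre_scr

    # physically-scaled starting points
    gcr = 1000.0
    krcrw = 0.0
    vd = None

    def pre_post(gcr_, vd_, kr_):
        params = creatinine_parameters(gcr_, vd_, kr_, patient)
        profile = simulate_week(schedule, params, patient)
        return (profile, predialysis_value(profile, schedule, idx),
                postdialysis_value(profile, schedule, idx))

    rate = excretion_rate(urine)
    lo, hi = vd_bracket

    def ratio_gap(vd_):
        _, pre, post = pre_post(gcr, vd_, krcrw)
        return post / pre - target_ratio

    for outer in range(1, max_outer + 1):
        vd = brentq(ratio_gap, lo, hi, xtol=1e-3)
        profile, pre, post = pre_post(gcr, vd, krcrw)
        scale = samples.pre_scr / pre
        gcr *= scale
        # linearity in G: the whole profile scales with gcr
        tac = time_averaged_water_concentration(
            profile, urine.start_minute, urine.end_minute) * scale
        kr_new = rate / tac
        done = abs(kr_new - krcrw) <= CLEARANCE_TOL_ML_MIN
        krcrw = kr_new
        if done:
            break
    else:
        raise RuntimeError(f"no convergence in {max_outer} outer iterations")

    # polish at the converged clearance so the reported fit is self-consistent
    vd = brentq(ratio_gap, lo, hi, xtol=1e-5)
    _, pre, _ = pre_post(gcr, vd, krcrw)
    gcr *= samples.pre_scr / pre
    profile, pre, post = pre_post(gcr, vd, krcrw)
    tac = time_averaged_water_concentration(profile, urine.start_minute,
                                            urine.end_minute)
    return ModelingResult(GCr=gcr, VdCr=vd, KrCrW=krcrw, predicted_pre=pre,
                          predicted_post=post, tac_water_window=tac,
                          iterations=outer,
                          converged=abs(pre - samples.pre_scr) <= CONC_TOL_MG_DL
                          and abs(post - samples.post_scr) <= CONC_TOL_MG_DL)


def spktv(pre_sun: float, post_sun: float, t: float, uf_volume: float,
          weight: float) -> float:
    """Single-pool Kt/V urea from the second-generation rate equation:
    ``-ln(R - 0.008 t) + (4 - 3.5 R) UF/W`` with ``R = post/pre``, session
    length ``t`` in hours, UF in litres, weight in kg. Convenience output
    only — no solver uses it."""
    if not 0 < post_sun < pre_sun:
        raise ValueError("need 0 < post < pre")
    if t <= 0:
        raise ValueError("t must be positive")
    r = post_sun / pre_sun
    arg = r - 0.008 * t
    if arg <= 0:
        raise ValueError("R - 0.008 t must be positive")
    return -math.log(arg) + (4.0 - 3.5 * r) * uf_volume / weight
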