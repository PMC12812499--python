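"""Synthetic study cohorts with internally consistent measurements.

No individual patient data are published for incremental-schedule cohorts
of this kind, so solver validation runs on synthetic patients drawn from
the study population's summary statistics: GCr 1091 ± 377 mg/day, VdCr
22.7 ± 2.4 L, urine-measured KrCrW 7.43 ± 4.07 mL/min, ultrafiltration
0.78 ± 0.79 L (1/wk) and 1.28 ± 0.88 L (2/wk), half the cohort on each
schedule. Distributions are normals truncated at physiologic bounds (only
mean ± SD being reported, the shape is a modeling choice).

Measurements are generated from each patient's own simulated steady state —
serum samples read off the profile, urine excretion integrated from
``Kr_water x C1`` over the interdialytic window — so with zero noise the
whole generate → measure → fit pipeline closes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .anthropometry import PatientProfile
from .kinetics import (DialysisSession, WeeklySchedule, WeeklyProfile,
                       WEEK_MINUTES, creatinine_parameters, predialysis_value,
                       postdialysis_value, simulate_week)
from .solvers import MeasuredSamples
from .urine import UrineCollection

__all__ = ["CohortSpec", "MeasurementNoise", "SyntheticPatient",
           "generate_cohort", "generate_measurements", "DEFAULT_SEED"]

DEFAULT_SEED = 20251003


@dataclass(frozen=True)
class MeasurementNoise:
    """Multiplicative measurement-error levels (coefficients of variation).

    ``lab_cv`` applies to each serum creatinine; ``collection_cv`` to each
    daily urine aliquot's recovered creatinine mass (incomplete or
    over-collection). Zero everywhere gives perfectly consistent data.
    """

    lab_cv: float = 0.02
    collection_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.lab_cv < 0 or self.collection_cv < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Sampling distributions for a synthetic incremental-HD cohort."""

    n_patients: int = 24
    frac_once_weekly: float = 0.5
    gcr_mean: float = 1091.0
    gcr_sd: float = 377.0
    gcr_min: float = 200.0
    vdcr_mean: float = 22.7
    vdcr_sd: float = 2.4
    vdcr_min: float = 10.0
    krcrw_mean: float = 7.43
    krcrw_sd: float = 4.07
    uf_mean_once: float = 0.78
    uf_sd_once: float = 0.79
    uf_mean_twice: float = 1.28
    uf_sd_twice: float = 0.88
    age_mean_once: float = 70.8
    age_sd_once: float = 13.2
    age_mean_twice: float = 68.0
    age_sd_twice: float = 7.6
    p_male_once: float = 9 / 12
    p_male_twice: float = 8 / 12
    vdcr_weight_ratio_mean: float = 0.35
    vdcr_weight_ratio_sd: float = 0.076
    height_mean: float = 168.0
    height_sd: float = 9.0
    noise: MeasurementNoise = field(default_factory=MeasurementNoise)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.frac_once_weekly <= 1:
            raise ValueError("frac_once_weekly must be in [0, 1]")
        for name in ("gcr_sd", "vdcr_sd", "krcrw_sd", "uf_sd_once",
                     "uf_sd_twice", "age_sd_once", "age_sd_twice",
                     "vdcr_weight_ratio_sd", "height_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SyntheticPatient:
    """One synthetic patient with ground-truth kinetic parameters."""

    patient_id: int
    patient: PatientProfile
    schedule: WeeklySchedule
    gcr_mg_day: float
    vdcr_l: float
    krcrw_ml_min: float


def _trunc_normal(rng, mean, sd, lower, upper=np.inf, size=None):
    if sd == 0:
        val = np.clip(mean, lower, upper if np.isfinite(upper) else mean)
        return np.full(size, val) if size is not None else float(val)
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _build_schedule(rng, once_weekly: bool, spec: CohortSpec) -> WeeklySchedule:
    if once_weekly:
        days = (0,)
        k0a = 800.0
        uf_mean, uf_sd = spec.uf_mean_once, spec.uf_sd_once
    else:
        # Monday-Friday or Tuesday-Saturday, as in the study
        days = (0, 4) if rng.random() < 0.5 else (1, 5)
        k0a = 950.0
        uf_mean, uf_sd = spec.uf_mean_twice, spec.uf_sd_twice
    sessions = [DialysisSession(day_index=d, start_minute_of_day=480,
                                duration=240, Qb=300.0, Qd=500.0,
                                k0a_invitro_urea=k0a,
                                uf_volume=float(_trunc_normal(rng, uf_mean,
                                                              uf_sd, 0.0)))
                for d in days]
    return WeeklySchedule(sessions, modeled_session_index=0)


def generate_cohort(spec: CohortSpec | None = None) -> list[SyntheticPatient]:
    """Draw a reproducible cohort; truth parameters retained for recovery
    tests. Patient weight is derived from the sampled VdCr through a sampled
    VdCr/weight ratio so that volumes and weights stay mutually consistent.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n_once = int(round(spec.n_patients * spec.frac_once_weekly))
    out: list[SyntheticPatient] = []
    for pid in range(spec.n_patients):
        once = pid < n_once
        gcr = float(_trunc_normal(rng, spec.gcr_mean, spec.gcr_sd, spec.gcr_min))
        vdcr = float(_trunc_normal(rng, spec.vdcr_mean, spec.vdcr_sd,
                                   spec.vdcr_min))
        krcrw = float(_trunc_normal(rng, spec.krcrw_mean, spec.krcrw_sd, 0.0))
        ratio = float(_trunc_normal(rng, spec.vdcr_weight_ratio_mean,
                                    spec.vdcr_weight_ratio_sd, 0.20, 0.55))
        weight = vdcr / ratio
        if once:
            age = float(_trunc_normal(rng, spec.age_mean_once,
                                      spec.age_sd_once, 18.0, 95.0))
            male = rng.random() < spec.p_male_once
        else:
            age = float(_trunc_normal(rng, spec.age_mean_twice,
                                      spec.age_sd_twice, 18.0, 95.0))
            male = rng.random() < spec.p_male_twice
        height = float(_trunc_normal(rng, spec.height_mean, spec.height_sd,
                                     140.0, 200.0))
        patient = PatientProfile(sex="male" if male else "female", age=age,
                                 weight_postdialysis=weight, height=height)
        schedule = _build_schedule(rng, once, spec)
        out.append(SyntheticPatient(patient_id=pid, patient=patient,
                                    schedule=schedule, gcr_mg_day=gcr,
                                    vdcr_l=vdcr, krcrw_ml_min=krcrw))
    return out


def generate_measurements(truth: SyntheticPatient,
                          noise: MeasurementNoise | None = None,
                          rng: np.random.Generator | None = None,
                          profile: WeeklyProfile | None = None,
                          ) -> tuple[MeasuredSamples, UrineCollection]:
    """Measurements a modeling session would record for this patient.

    Serum pre/post creatinine are read off the patient's true steady-state
    profile with multiplicative lab noise; urine is the integral of the true
    ``Kr_water x C1`` over the full interdialytic interval preceding the
    modeled session, in daily aliquots (the final aliquot spanning exactly
    the last 24 h), each perturbed by collection noise. Non-positive noisy
    values are redrawn.
    """
    noise = noise if noise is not None else MeasurementNoise()
    rng = rng if rng is not None else np.random.default_rng(DEFAULT_SEED)
    params = creatinine_parameters(truth.gcr_mg_day, truth.vdcr_l,
                                   truth.krcrw_ml_min, truth.patient)
    if profile is None:
        profile = simulate_week(truth.schedule, params, truth.patient)

    def noisy(value, cv):
        if cv == 0:
            return value
        for _ in range(100):
            v = value * (1.0 + cv * rng.standard_normal())
            if v > 0:
                return v
        raise RuntimeError("noise kept producing non-positive values")

    pre = noisy(predialysis_value(profile, truth.schedule), noise.lab_cv)
    post_true = postdialysis_value(profile, truth.schedule)
    post = min(noisy(post_true, noise.lab_cv), 0.999 * pre)
    samples = MeasuredSamples(pre_scr=pre, post_scr=post,
                              sample_session_index=truth.schedule.modeled_session_index)

    w0, w1 = truth.schedule.interdialytic_window()
    # daily aliquots, tiled backward so the last spans exactly 24 h
    bounds = list(range(w1, w0, -1440))[::-1]
    if bounds[0] != w0:
        bounds.insert(0, w0)
    c1 = profile.C1
    kr = truth.krcrw_ml_min
    aliquots = []
    for s, e in zip(bounds, bounds[1:]):
        idx = np.arange(s, e) % WEEK_MINUTES
        mass = kr * float(c1[idx].sum())  # mL/min * mg/mL * min = mg
        mass = noisy(mass, noise.collection_cv) if mass > 0 else mass
        rate_ml_min = float(_trunc_normal(rng, 0.7, 0.2, 0.1))
        volume = rate_ml_min * (e - s)
        conc = mass / volume * 100.0  # mg/dL
        if conc <= 0:
            conc = 1e-6  # anuric patients still produce a (blank) sample
        aliquots.append(UrineCollection(start_minute=s, end_minute=e,
                                        volume=volume, creatinine_conc=conc))
    total_volume = sum(a.volume for a in aliquots)
    total_mass = sum(a.creatinine_mass for a in aliquots)
    pooled = UrineCollection(start_minute=w0, end_minute=w1,
                             volume=total_volume,
                             creatinine_conc=max(total_mass / total_volume * 100.0,
                                                 1e-6),
                             aliquots=tuple(aliquots))
    return samples, pooled
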