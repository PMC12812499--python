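"""Two-pool variable-volume solute kinetics over a periodic dialysis week.

The solute (urea or creatinine) distributes over a proximal pool — the one
the dialyzer, residual kidney, and extrarenal routes clear — and a distal
pool where generation enters (creatinine is made in muscle, remote from the
sampled compartment). The pools exchange through an intercompartmental
clearance proportional to body weight. Total distribution volume falls
linearly during each session by the session's ultrafiltration volume and is
regained at a constant drinking rate spread over all interdialytic minutes,
so the weekly fluid balance closes exactly.

Concentrations are carried internally per mL of *water*; plasma values are
obtained by multiplying by the plasma water fraction (0.93 at 7% protein,
i.e. dividing by ~1.075).

Integration is an explicit walk over the 10080 minutes of the week. Within
each minute the coefficients (volumes, clearances) are frozen at their
mid-minute values and the resulting constant-coefficient linear 2x2 system
is advanced *exactly* via its matrix exponential, so the stepping is stable
for arbitrarily stiff intercompartmental exchange. The 10080 exact minute
maps compose into a single affine weekly map; the periodic steady state is
found by fixed-point iteration of that map (cap 200 weeks, tolerance 1e-6
mg/mL on the start-of-week concentrations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anthropometry import PatientProfile
from .dialyzer import (FlowContext, K0A_INVIVO_FACTORS,
                       michaels_diffusive_clearance, solute_flow,
                       uf_adjusted_clearance)

__all__ = [
    "WEEK_MINUTES",
    "SoluteParameters",
    "DialysisSession",
    "WeeklySchedule",
    "WeeklyProfile",
    "WeekIntegrator",
    "ConvergenceError",
    "simulate_week",
    "predialysis_value",
    "postdialysis_value",
    "time_averaged_water_concentration",
    "creatinine_parameters",
    "urea_parameters",
]

WEEK_MINUTES = 10080

#: Default intercompartmental clearance per kg postdialysis weight, mL/min/kg.
DEFAULT_KC_PER_KG = 8.0
#: Default proximal (extracellular-like) share of the distribution volume.
DEFAULT_PROXIMAL_FRACTION = 1.0 / 3.0
#: Default extrarenal creatinine water clearance, L/day per kg weight
#: (gut degradation; ~1.8 mL/min at 70 kg).
DEFAULT_KE_CREATININE_L_DAY_KG = 0.038


class ConvergenceError(RuntimeError):
    """Weekly fixed-point iteration failed to reach a periodic steady state."""


@dataclass(frozen=True)
class SoluteParameters:
    """Kinetic constants for one solute.

    Attributes
    ----------
    solute_name : {"urea", "creatinine"}
    G : generation rate entering the distal pool, mg/min
    Vd : total distribution volume (both pools), L
    Kr_water : residual kidney water clearance, mL/min
    Ke_water : extrarenal (non-renal, non-dialyzer) water clearance, mL/min
    Kc_per_kg : intercompartmental clearance per kg postdialysis weight
    proximal_fraction : share of Vd in the proximal pool
    k0a_invivo_factor : in-vitro->in-vivo K0A derating; resolved from the
        solute name when left as None
    """

    solute_name: str
    G: float
    Vd: float
    Kr_water: float = 0.0
    Ke_water: float = 0.0
    Kc_per_kg: float = DEFAULT_KC_PER_KG
    proximal_fraction: float = DEFAULT_PROXIMAL_FRACTION
    k0a_invivo_factor: float | None = None

    def __post_init__(self) -> None:
        if self.solute_name not in ("urea", "creatinine"):
            raise ValueError(f"unknown solute {self.solute_name!r}")
        if self.G < 0:
            raise ValueError("G must be non-negative")
        if self.Vd <= 0:
            raise ValueError("Vd must be positive")
        if self.Kr_water < 0 or self.Ke_water < 0:
            raise ValueError("clearances must be non-negative")
        if not 0 < self.proximal_fraction < 1:
            raise ValueError("proximal_fraction must be in (0, 1)")
        f = self.resolved_k0a_factor
        if not 0 < f <= 1:
            raise ValueError("k0a_invivo_factor must be in (0, 1]")

    @property
    def resolved_k0a_factor(self) -> float:
        if self.k0a_invivo_factor is not None:
            return self.k0a_invivo_factor
        return K0A_INVIVO_FACTORS[self.solute_name]


def creatinine_parameters(gcr_mg_day: float, vdcr_l: float, krcrw: float,
                          patient: PatientProfile, *,
                          ke_l_day_per_kg: float = DEFAULT_KE_CREATININE_L_DAY_KG,
                          kc_per_kg: float = DEFAULT_KC_PER_KG,
                          proximal_fraction: float = DEFAULT_PROXIMAL_FRACTION,
                          ) -> SoluteParameters:
    """Creatinine :class:`SoluteParameters` from clinical-unit inputs
    (GCr in mg/day, KrCrW in mL/min), with the extrarenal clearance scaled
    to the patient's postdialysis weight."""
    ke = ke_l_day_per_kg * patient.weight_postdialysis * 1000.0 / 1440.0
    return SoluteParameters("creatinine", G=gcr_mg_day / 1440.0, Vd=vdcr_l,
                            Kr_water=krcrw, Ke_water=ke,
                            Kc_per_kg=kc_per_kg,
                            proximal_fraction=proximal_fraction)


def urea_parameters(g_mg_day: float, vd_l: float, kr_water: float,
                    patient: PatientProfile, *,
                    kc_per_kg: float = DEFAULT_KC_PER_KG,
                    proximal_fraction: float = DEFAULT_PROXIMAL_FRACTION,
                    ) -> SoluteParameters:
    """Urea :class:`SoluteParameters`; extrarenal clearance defaults to 0."""
    return SoluteParameters("urea", G=g_mg_day / 1440.0, Vd=vd_l,
                            Kr_water=kr_water, Ke_water=0.0,
                            Kc_per_kg=kc_per_kg,
                            proximal_fraction=proximal_fraction)


@dataclass(frozen=True)
class DialysisSession:
    """One hemodialysis treatment placed in the week.

    ``day_index`` 0 = Monday; times are 0-based minutes, the session occupies
    the half-open interval ``[start_minute, start_minute + duration)``.
    """

    day_index: int
    start_minute_of_day: int
    duration: int
    Qb: float
    Qd: float
    k0a_invitro_urea: float
    uf_volume: float  # L

    def __post_init__(self) -> None:
        if not 0 <= self.day_index <= 6:
            raise ValueError("day_index must be 0..6")
        if not 0 <= self.start_minute_of_day < 1440:
            raise ValueError("start_minute_of_day must be in [0, 1440)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.Qb <= 0 or self.Qd <= 0:
            raise ValueError("flows must be positive")
        if self.k0a_invitro_urea <= 0:
            raise ValueError("k0a_invitro_urea must be positive")
        if self.uf_volume < 0:
            raise ValueError("uf_volume must be non-negative")

    @property
    def start_minute(self) -> int:
        """Absolute start minute within the week."""
        return self.day_index * 1440 + self.start_minute_of_day

    @property
    def end_minute(self) -> int:
        return self.start_minute + self.duration

    @property
    def uf_rate(self) -> float:
        """Ultrafiltration rate, mL/min, constant within the session."""
        return self.uf_volume * 1000.0 / self.duration


@dataclass(frozen=True)
class WeeklySchedule:
    """Ordered, non-overlapping sessions in a 10080-minute periodic week."""

    sessions: tuple[DialysisSession, ...]
    modeled_session_index: int = 0

    def __init__(self, sessions, modeled_session_index: int = 0):
        sessions = tuple(sorted(sessions, key=lambda s: s.start_minute))
        object.__setattr__(self, "sessions", sessions)
        object.__setattr__(self, "modeled_session_index", modeled_session_index)
        self._validate()

    def _validate(self) -> None:
        n = len(self.sessions)
        if n > 7:
            raise ValueError("at most 7 sessions per week")
        if n and not 0 <= self.modeled_session_index < n:
            raise ValueError("modeled_session_index out of range")
        for i, s in enumerate(self.sessions):
            if s.end_minute > WEEK_MINUTES:
                raise ValueError("session runs past the end of the week")
            if i + 1 < n and s.end_minute > self.sessions[i + 1].start_minute:
                raise ValueError("sessions overlap")

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def total_session_minutes(self) -> int:
        return sum(s.duration for s in self.sessions)

    @property
    def total_uf_volume(self) -> float:
        return sum(s.uf_volume for s in self.sessions)

    def interdialytic_window(self, session_index: int | None = None
                             ) -> tuple[int, int]:
        """Absolute-minute window from the end of the preceding session to
        the start of ``session_index`` (default: the modeled session). The
        end bound may exceed 10080 when the window wraps the week boundary.
        """
        if not self.sessions:
            raise ValueError("schedule has no sessions")
        i = self.modeled_session_index if session_index is None else session_index
        s = self.sessions[i]
        prev = self.sessions[i - 1]  # wraps to the last session when i == 0
        start = prev.end_minute
        end = s.start_minute
        if end <= start:
            end += WEEK_MINUTES
        return start, end


@dataclass
class WeeklyProfile:
    """Minute-resolution periodic steady state over one week.

    ``C1``/``C2`` are proximal/distal water concentrations (mg/mL water) at
    each minute boundary 0..10079; ``V_total`` the total distribution volume
    (L). ``plasma_water_fraction`` converts water to plasma concentrations.
    """

    C1: np.ndarray
    C2: np.ndarray
    V_total: np.ndarray
    converged: bool
    weeks_to_converge: int
    plasma_water_fraction: float = 0.93
    removal_dialyzer_mg: float = 0.0
    removal_kidney_mg: float = 0.0
    removal_extrarenal_mg: float = 0.0
    periodicity_gap: float = field(default=0.0, repr=False)

    def plasma_mg_dl(self, minute: int) -> float:
        """Proximal plasma concentration (mg/dL) at a minute boundary."""
        return float(self.C1[minute % WEEK_MINUTES]) * self.plasma_water_fraction * 100.0


class WeekIntegrator:
    """Precomputed exact minute-by-minute propagator for one parameter set.

    Builds, once, the per-minute affine updates ``x -> E_n x + b_n`` of the
    pool masses ``x = (M1, M2)`` (mg) and exposes week-level operations:
    open-loop propagation, the composed weekly affine map, and the periodic
    steady state.
    """

    def __init__(self, schedule: WeeklySchedule, params: SoluteParameters,
                 patient: PatientProfile):
        self.schedule = schedule
        self.params = params
        self.patient = patient
        self._build()

    # -- construction -----------------------------------------------------

    def _build(self) -> None:
        p, sched, patient = self.params, self.schedule, self.patient
        vd_ml = p.Vd * 1000.0

        slope = np.zeros(WEEK_MINUTES)  # dV/dt, mL/min
        clear = np.full(WEEK_MINUTES, p.Kr_water + p.Ke_water)  # mL/min on C1
        total_session_min = sched.total_session_minutes
        idle_min = WEEK_MINUTES - total_session_min
        intake = (sched.total_uf_volume * 1000.0 / idle_min) if idle_min else 0.0
        slope[:] = intake
        for s in sched.sessions:
            sl = slice(s.start_minute, s.end_minute)
            slope[sl] = -s.uf_rate
            ctx = FlowContext(Qb=s.Qb, Qd=s.Qd, hematocrit=patient.hematocrit,
                              Quf=s.uf_rate)
            k0a = s.k0a_invitro_urea * p.resolved_k0a_factor
            qw = solute_flow(ctx, p.solute_name)
            kd = uf_adjusted_clearance(
                michaels_diffusive_clearance(k0a, qw, s.Qd), qw, s.uf_rate)
            clear[sl] += kd

        # volume at minute boundaries, anchored so that V equals Vd at the
        # end of the modeled session (postdialysis volume convention)
        v = np.concatenate([[0.0], np.cumsum(slope)])
        if sched.sessions:
            anchor = sched.sessions[sched.modeled_session_index].end_minute
        else:
            anchor = 0
        v += vd_ml - v[anchor % WEEK_MINUTES]
        if abs(v[-1] - v[0]) > 1e-6 * vd_ml:
            raise ValueError("weekly fluid balance failed to close")
        if v.min() <= 0.05 * vd_ml:
            raise ValueError("ultrafiltration drives volume near zero")
        self.V = v  # length 10081, mL
        self.clearance = clear  # per-minute total water clearance on C1

        f = p.proximal_fraction
        vmid = 0.5 * (v[:-1] + v[1:])
        v1 = f * vmid
        v2 = (1.0 - f) * vmid
        kc = p.Kc_per_kg * patient.weight_postdialysis

        a = -(kc + clear) / v1
        b = kc / v2
        c = kc / v1
        d = -kc / v2
        E, B = _exact_minute_maps(a, b, c, d, p.G)
        self._E = E  # (10080, 2, 2)
        self._B = B  # (10080, 2)
        # flat python lists for the tight per-minute loops
        self._e11, self._e12 = E[:, 0, 0].tolist(), E[:, 0, 1].tolist()
        self._e21, self._e22 = E[:, 1, 0].tolist(), E[:, 1, 1].tolist()
        self._b1, self._b2 = B[:, 0].tolist(), B[:, 1].tolist()

    # -- week-level operations -------------------------------------------

    def weekly_affine_map(self) -> tuple[np.ndarray, np.ndarray]:
        """Compose the 10080 minute maps into ``x -> A x + b`` over one week."""
        if not hasattr(self, "_weekly"):
            a11, a12, a21, a22 = 1.0, 0.0, 0.0, 1.0
            w1 = w2 = 0.0
            e11, e12, e21, e22 = self._e11, self._e12, self._e21, self._e22
            b1, b2 = self._b1, self._b2
            for n in range(WEEK_MINUTES):
                f11, f12, f21, f22 = e11[n], e12[n], e21[n], e22[n]
                a11, a12, a21, a22 = (f11 * a11 + f12 * a21,
                                      f11 * a12 + f12 * a22,
                                      f21 * a11 + f22 * a21,
                                      f21 * a12 + f22 * a22)
                w1, w2 = (f11 * w1 + f12 * w2 + b1[n],
                          f21 * w1 + f22 * w2 + b2[n])
            self._weekly = (np.array([[a11, a12], [a21, a22]]),
                            np.array([w1, w2]))
        return self._weekly

    def run_week(self, x0: tuple[float, float], record: bool = False):
        """Propagate masses over one week from ``x0``.

        Returns ``x_end`` or, with ``record``, ``(M1, M2)`` arrays of the
        10081 minute-boundary states.
        """
        m1, m2 = float(x0[0]), float(x0[1])
        e11, e12, e21, e22 = self._e11, self._e12, self._e21, self._e22
        b1, b2 = self._b1, self._b2
        if not record:
            for n in range(WEEK_MINUTES):
                m1, m2 = (e11[n] * m1 + e12[n] * m2 + b1[n],
                          e21[n] * m1 + e22[n] * m2 + b2[n])
            return m1, m2
        out1 = [0.0] * (WEEK_MINUTES + 1)
        out2 = [0.0] * (WEEK_MINUTES + 1)
        out1[0], out2[0] = m1, m2
        for n in range(WEEK_MINUTES):
            m1, m2 = (e11[n] * m1 + e12[n] * m2 + b1[n],
                      e21[n] * m1 + e22[n] * m2 + b2[n])
            out1[n + 1], out2[n + 1] = m1, m2
        return np.asarray(out1), np.asarray(out2)

    def steady_state(self, conc_tol: float = 1e-6, max_weeks: int = 200
                     ) -> tuple[tuple[float, float], int]:
        """Fixed-point week iteration to the periodic steady state.

        Returns the start-of-week masses and the number of weeks iterated.
        Raises :class:`ConvergenceError` at the cap (e.g. generation with no
        clearance anywhere, which has no steady state).
        """
        A, b = self.weekly_affine_map()
        p = self.params
        ktot = float(self.clearance.sum())  # mL (clearance-minutes)
        c0 = (p.G * WEEK_MINUTES / ktot) if ktot > 0 else 0.0
        f = p.proximal_fraction
        v0 = self.V[0]
        x = np.array([c0 * f * v0, c0 * (1 - f) * v0])
        vref = np.array([f * v0, (1 - f) * v0])
        for week in range(1, max_weeks + 1):
            xn = A @ x + b
            if np.max(np.abs(xn - x) / vref) < conc_tol:
                return (float(xn[0]), float(xn[1])), week
            x = xn
        raise ConvergenceError(
            f"no periodic steady state after {max_weeks} weeks "
            "(check that at least one clearance is positive)")


def simulate_week(schedule: WeeklySchedule, params: SoluteParameters,
                  patient: PatientProfile, *, conc_tol: float = 1e-6,
                  max_weeks: int = 200) -> WeeklyProfile:
    """Simulate the weekly periodic steady state of the two-pool model.

    Repeats the weekly cycle from a rough initial concentration until
    successive weeks agree within ``conc_tol`` mg/mL, then records the
    converged minute-by-minute profile.
    """
    integ = WeekIntegrator(schedule, params, patient)
    x_ss, weeks = integ.steady_state(conc_tol=conc_tol, max_weeks=max_weeks)
    m1, m2 = integ.run_week(x_ss, record=True)
    f = params.proximal_fraction
    v = integ.V
    c1 = m1[:-1] / (f * v[:-1])
    c2 = m2[:-1] / ((1 - f) * v[:-1])
    if params.G > 0 and (np.any(c1 <= 0) or np.any(c2 <= 0)):
        raise ConvergenceError("non-positive concentration at steady state")
    gap = max(abs(m1[-1] - m1[0]) / (f * v[0]),
              abs(m2[-1] - m2[0]) / ((1 - f) * v[0]))

    # exact removal split: per-minute removed mass = G*dt - d(M1+M2)
    mtot = m1 + m2
    removed = params.G - np.diff(mtot)  # mg per minute, all clearance routes
    ktot = integ.clearance
    base = params.Kr_water + params.Ke_water
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(ktot > 0, removed / ktot, 0.0)  # = integral of C1 dt
    kidney = params.Kr_water * share
    extrarenal = params.Ke_water * share
    dial = (ktot - base) * share
    return WeeklyProfile(
        C1=c1, C2=c2, V_total=v[:-1] / 1000.0, converged=True,
        weeks_to_converge=weeks,
        plasma_water_fraction=patient.plasma_water_fraction,
        removal_dialyzer_mg=float(dial.sum()),
        removal_kidney_mg=float(kidney.sum()),
        removal_extrarenal_mg=float(extrarenal.sum()),
        periodicity_gap=float(gap),
    )


def predialysis_value(profile: WeeklyProfile, schedule: WeeklySchedule,
                      session_index: int | None = None) -> float:
    """Predialysis plasma concentration (mg/dL) for a session: the proximal
    concentration at the minute the session starts, converted from water to
    plasma."""
    if not profile.converged:
        raise ValueError("profile has not converged")
    i = schedule.modeled_session_index if session_index is None else session_index
    if not 0 <= i < schedule.n_sessions:
        raise IndexError("session_index out of range")
    return profile.plasma_mg_dl(schedule.sessions[i].start_minute)


def postdialysis_value(profile: WeeklyProfile, schedule: WeeklySchedule,
                       session_index: int | None = None) -> float:
    """Postdialysis plasma concentration (mg/dL): proximal concentration at
    the session's end minute (no rebound sampling delay)."""
    if not profile.converged:
        raise ValueError("profile has not converged")
    i = schedule.modeled_session_index if session_index is None else session_index
    if not 0 <= i < schedule.n_sessions:
        raise IndexError("session_index out of range")
    return profile.plasma_mg_dl(schedule.sessions[i].end_minute)


def time_averaged_water_concentration(profile: WeeklyProfile,
                                      window_start_minute: int,
                                      window_end_minute: int) -> float:
    """Arithmetic mean of the proximal water concentration (mg/mL) over
    ``[start, end)`` in absolute week minutes; the window may wrap past
    10080 (end expressed beyond the week boundary)."""
    n = window_end_minute - window_start_minute
    if n <= 0:
        raise ValueError("window must have positive length")
    if n > WEEK_MINUTES:
        raise ValueError("window longer than one week")
    idx = np.arange(window_start_minute, window_end_minute) % WEEK_MINUTES
    return float(profile.C1[idx].mean())


# ---------------------------------------------------------------------------

def _exact_minute_maps(a, b, c, d, G):
    """Exact one-minute propagators of ``dx/dt = Q x + (0, G)`` per minute.

    ``Q = [[a, b], [c, d]]`` has real eigenvalues for compartmental systems
    (``(a-d)^2 + 4bc >= 0`` since ``b, c >= 0``). Returns ``E = expm(Q)``
    (shape (n,2,2)) and ``B = phi1(Q) @ (0,G)`` with
    ``phi1(Q) = integral_0^1 expm(Q s) ds``, via the spectral decomposition;
    the (measure-zero) defective case ``Q ~ 0`` falls back to a Taylor
    expansion.
    """
    a = np.asarray(a, dtype=float)
    tr = a + d
    disc = (a - d) ** 2 + 4.0 * b * c
    sq = np.sqrt(np.maximum(disc, 0.0))
    lam1 = 0.5 * (tr + sq)
    lam2 = 0.5 * (tr - sq)

    def _phi(l):
        small = np.abs(l) < 1e-9
        safe = np.where(small, 1.0, l)
        return np.where(small, 1.0 + l / 2.0, np.expm1(safe) / safe)

    e1, e2 = np.exp(lam1), np.exp(lam2)
    f1, f2 = _phi(lam1), _phi(lam2)

    deg = sq < 1e-12
    ssafe = np.where(deg, 1.0, sq)

    def _mat(alpha, beta):
        # alpha * P1 + beta * P2, P1 = (Q - lam2 I)/sq, P2 = (lam1 I - Q)/sq
        m11 = (alpha * (a - lam2) + beta * (lam1 - a)) / ssafe
        m12 = (alpha - beta) * b / ssafe
        m21 = (alpha - beta) * c / ssafe
        m22 = (alpha * (d - lam2) + beta * (lam1 - d)) / ssafe
        return m11, m12, m21, m22

    E11, E12, E21, E22 = _mat(e1, e2)
    P11, P12, P21, P22 = _mat(f1, f2)

    if np.any(deg):  # Q ~ 0: E = I + Q + Q^2/2, phi1 = I + Q/2 + Q^2/6
        q11, q12, q21, q22 = a, np.broadcast_to(b, a.shape), \
            np.broadcast_to(c, a.shape), np.broadcast_to(d, a.shape)
        s11 = q11 * q11 + q12 * q21
        s12 = q11 * q12 + q12 * q22
        s21 = q21 * q11 + q22 * q21
        s22 = q21 * q12 + q22 * q22
        E11 = np.where(deg, 1.0 + q11 + s11 / 2, E11)
        E12 = np.where(deg, q12 + s12 / 2, E12)
        E21 = np.where(deg, q21 + s21 / 2, E21)
        E22 = np.where(deg, 1.0 + q22 + s22 / 2, E22)
        P11 = np.where(deg, 1.0 + q11 / 2 + s11 / 6, P11)
        P12 = np.where(deg, q12 / 2 + s12 / 6, P12)
        P21 = np.where(deg, q21 / 2 + s21 / 6, P21)
        P22 = np.where(deg, 1.0 + q22 / 2 + s22 / 6, P22)

    n = a.shape[0]
    E = np.empty((n, 2, 2))
    E[:, 0, 0], E[:, 0, 1], E[:, 1, 0], E[:, 1, 1] = E11, E12, E21, E22
    B = np.empty((n, 2))
    B[:, 0] = P12 * G
    B[:, 1] = P22 * G
    return E, B
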