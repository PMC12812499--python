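"""Urine-collection-based residual kidney creatinine water clearance.

The classic clearance: average excretion rate over a timed collection
divided by the concentration driving it. Because serum creatinine swings
over the interdialytic interval, the denominator is the *time-averaged*
proximal water concentration over the exact collection window, read off the
modeled weekly steady-state profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kinetics import (WEEK_MINUTES, WeeklyProfile,
                       time_averaged_water_concentration)

__all__ = ["UrineCollection", "excretion_rate", "krcrw_from_urine",
           "compare_collection_modes"]


@dataclass(frozen=True)
class UrineCollection:
    """A timed urine collection located in the dialysis week.

    ``start_minute``/``end_minute`` are absolute week minutes (end may run
    past 10080 when the window wraps the week boundary). ``creatinine_conc``
    is in mg/dL, the clinical lab convention. ``aliquots`` optionally holds
    daily sub-collections that tile the parent window.
    """

    start_minute: int
    end_minute: int
    volume: float  # mL
    creatinine_conc: float  # mg/dL
    aliquots: tuple["UrineCollection", ...] = field(default=())

    def __post_init__(self) -> None:
        if self.end_minute <= self.start_minute:
            raise ValueError("end_minute must exceed start_minute")
        if self.end_minute - self.start_minute > WEEK_MINUTES:
            raise ValueError("collection window longer than one week")
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.creatinine_conc <= 0:
            raise ValueError("creatinine_conc must be positive")
        if self.aliquots:
            spans = sorted((a.start_minute, a.end_minute) for a in self.aliquots)
            if spans[0][0] != self.start_minute or spans[-1][1] != self.end_minute:
                raise ValueError("aliquots do not span the parent window")
            for (s0, e0), (s1, _) in zip(spans, spans[1:]):
                if e0 != s1:
                    raise ValueError("aliquot windows must tile without gaps")

    @property
    def duration(self) -> int:
        return self.end_minute - self.start_minute

    @property
    def creatinine_mass(self) -> float:
        """Total creatinine excreted, mg (conc mg/dL x volume mL / 100)."""
        return self.creatinine_conc / 100.0 * self.volume

    def last_24h(self) -> "UrineCollection":
        """The final 24-hour aliquot (requires aliquots; the last one must
        span exactly the 1440 min preceding the window end)."""
        if not self.aliquots:
            raise ValueError("collection has no aliquots")
        last = max(self.aliquots, key=lambda a: a.end_minute)
        if last.duration != 1440:
            raise ValueError("final aliquot does not span 24 h")
        return last


def excretion_rate(c: UrineCollection) -> float:
    """Average creatinine excretion rate over the collection, mg/min."""
    return c.creatinine_mass / c.duration


def krcrw_from_urine(c: UrineCollection, profile: WeeklyProfile) -> float:
    """Residual kidney creatinine *water* clearance, mL/min.

    Excretion rate divided by the time-averaged serum water concentration
    over the collection window (from the modeled weekly profile). Multiply
    by ~1.075 for a conventional plasma clearance.
    """
    if not profile.converged:
        raise ValueError("profile has not converged")
    tac = time_averaged_water_concentration(profile, c.start_minute, c.end_minute)
    return excretion_rate(c) / tac


def compare_collection_modes(daily_last24h: UrineCollection,
                             pooled_full_interval: UrineCollection,
                             profile: WeeklyProfile) -> tuple[float, float]:
    """KrCrW computed two ways for the same patient: from the most recent
    24-h aliquot and from the pooled full-interval collection. Returns
    ``(last24h, pooled)`` in mL/min; real collections typically differ a
    little, and a declining diuresis pushes the 24-h value below the pooled
    one."""
    return (krcrw_from_urine(daily_last24h, profile),
            krcrw_from_urine(pooled_full_interval, profile))
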