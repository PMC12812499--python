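"""In-vivo dialyzer clearance from in-vitro K0A urea.

The chain is: derate the in-vitro mass-transfer-area coefficient to the
in-vivo situation (solute-specific factor), evaluate the Michaels
counter-current exchanger equation on the solute's water flow, then add the
convective contribution of ultrafiltration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FlowContext",
    "K0A_INVIVO_FACTORS",
    "RBC_WATER_FRACTION",
    "PLASMA_WATER_FRACTION",
    "invivo_k0a",
    "solute_flow",
    "michaels_diffusive_clearance",
    "uf_adjusted_clearance",
    "session_water_clearance",
]

#: In-vivo derating of the in-vitro K0A urea, per solute. The creatinine
#: factor also absorbs creatinine's lower membrane permeability.
K0A_INVIVO_FACTORS = {"urea": 0.537, "creatinine": 0.360}

RBC_WATER_FRACTION = 0.72     # water fraction of red cells
PLASMA_WATER_FRACTION = 0.93  # water fraction of plasma at ~7% protein


@dataclass(frozen=True)
class FlowContext:
    """Per-session flows seen by the dialyzer.

    Attributes
    ----------
    Qb : blood flow, mL/min
    Qd : dialysate flow, mL/min
    hematocrit : fraction of blood volume that is red cells
    Quf : ultrafiltration rate, mL/min
    """

    Qb: float
    Qd: float
    hematocrit: float = 0.30
    Quf: float = 0.0

    def __post_init__(self) -> None:
        if self.Qb <= 0 or self.Qd <= 0:
            raise ValueError("Qb and Qd must be positive")
        if not 0 <= self.hematocrit < 1:
            raise ValueError("hematocrit must be in [0, 1)")
        if self.Quf < 0:
            raise ValueError("Quf must be non-negative")


def invivo_k0a(k0a_invitro_urea: float, solute: str) -> float:
    """Derate an in-vitro K0A urea (mL/min) to in-vivo for the given solute
    (x0.537 for urea, x0.360 for creatinine)."""
    if k0a_invitro_urea <= 0:
        raise ValueError("k0a_invitro_urea must be positive")
    try:
        return k0a_invitro_urea * K0A_INVIVO_FACTORS[solute]
    except KeyError:
        raise ValueError(f"unknown solute {solute!r}") from None


def solute_flow(ctx: FlowContext, solute: str) -> float:
    """Effective water flow (mL/min) carrying the solute through the dialyzer.

    Urea equilibrates rapidly with red-cell water, so its carrier flow is
    blood water, ``Qb (0.72 Hct + 0.93 (1-Hct))``. Creatinine does not
    equilibrate with red cells within a single pass, so only plasma water
    counts: ``0.93 Qb (1-Hct)``.
    """
    h = ctx.hematocrit
    if solute == "urea":
        return ctx.Qb * (RBC_WATER_FRACTION * h + PLASMA_WATER_FRACTION * (1 - h))
    if solute == "creatinine":
        return ctx.Qb * PLASMA_WATER_FRACTION * (1 - h)
    raise ValueError(f"unknown solute {solute!r}")


def michaels_diffusive_clearance(k0a: float, Qw: float, Qd: float) -> float:
    """Diffusive clearance (mL/min) of an ideal counter-current exchanger.

    ``Kd = Qw (e^N - 1) / (e^N - Qw/Qd)`` with
    ``N = k0a (Qd - Qw) / (Qw Qd)``; at matched flows the limit
    ``Kd = Qw k0a / (k0a + Qw)`` applies.
    """
    if k0a <= 0 or Qw <= 0 or Qd <= 0:
        raise ValueError("k0a, Qw and Qd must be positive")
    if math.isclose(Qw, Qd, rel_tol=1e-12):
        return Qw * k0a / (k0a + Qw)
    n = k0a * (Qd - Qw) / (Qw * Qd)
    try:
        en = math.exp(n)
    except OverflowError:
        return min(Qw, Qd)
    if math.isinf(en):
        return min(Qw, Qd)
    return Qw * (en - 1.0) / (en - Qw / Qd)


def uf_adjusted_clearance(kd_diffusive: float, Qw: float, Quf: float) -> float:
    """Add the convective (ultrafiltration) contribution:
    ``Kd_total = Kd + Quf (1 - Kd/Qw)``.

    Solute already extracted diffusively cannot be removed again by the
    filtered fluid, hence the transmittance weighting of Quf.
    """
    if not 0 <= kd_diffusive <= Qw * (1 + 1e-12):
        raise ValueError("kd_diffusive must lie in [0, Qw]")
    if Quf < 0:
        raise ValueError("Quf must be non-negative")
    if Quf > Qw:
        raise ValueError("Quf exceeds the solute water flow (nonphysical)")
    return kd_diffusive + Quf * (1.0 - kd_diffusive / Qw)


def session_water_clearance(k0a_invitro_urea: float, solute: str,
                            ctx: FlowContext) -> float:
    """Full chain for one session: in-vivo K0A -> Michaels on the solute's
    water flow -> UF adjustment. Returns total water clearance, mL/min."""
    k0a = invivo_k0a(k0a_invitro_urea, solute)
    qw = solute_flow(ctx, solute)
    kd = michaels_diffusive_clearance(k0a, qw, ctx.Qd)
    return uf_adjusted_clearance(kd, qw, ctx.Quf)
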