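"""Independent numerical oracles, deliberately naive.

These re-derive the package's quantities by brute force — a 1-second Euler
walk of the two-pool ODEs and a shooting solution of the counter-current
exchanger boundary-value problem — sharing no code with the implementation
paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from hdkinetics import WEEK_MINUTES, WeekIntegrator


def euler_week_1s(integ: WeekIntegrator, x0, substeps: int = 60):
    """Propagate pool masses over one week with forward-Euler sub-minute
    steps, using the same piecewise-linear volume and per-minute clearance
    as the integrator but none of its exponential-update machinery.

    Returns (M1, M2) at the 10081 minute boundaries.
    """
    p = integ.params
    f = p.proximal_fraction
    kc = p.Kc_per_kg * integ.patient.weight_postdialysis
    V = integ.V  # mL at minute boundaries
    K = integ.clearance
    dt = 1.0 / substeps
    m1, m2 = float(x0[0]), float(x0[1])
    out1 = np.empty(WEEK_MINUTES + 1)
    out2 = np.empty(WEEK_MINUTES + 1)
    out1[0], out2[0] = m1, m2
    for n in range(WEEK_MINUTES):
        v0, v1 = V[n], V[n + 1]
        k = K[n]
        for j in range(substeps):
            v = v0 + (v1 - v0) * (j + 0.5) * dt
            c1 = m1 / (f * v)
            c2 = m2 / ((1 - f) * v)
            flux = kc * (c2 - c1)
            m1 += (flux - k * c1) * dt
            m2 += (p.G - flux) * dt
        out1[n + 1], out2[n + 1] = m1, m2
    return out1, out2


def countercurrent_clearance(k0a: float, Qw: float, Qd: float) -> float:
    """Diffusive clearance of a counter-current exchanger by solving the
    axial two-point boundary-value problem with a shooting method.

    Blood water (flow Qw) enters at z=0 with concentration 1; dialysate
    (flow Qd) enters at z=1 with concentration 0. Along the fiber:
    ``Qw dCb/dz = -k0a (Cb - Cd)`` and ``Qd dCd/dz = -k0a (Cb - Cd)``.
    The problem is linear, so two trial integrations fix the dialysate
    concentration at z=0.
    """

    def rhs(_z, y):
        cb, cd = y
        j = k0a * (cb - cd)
        return [-j / Qw, -j / Qd]

    def shoot(cd0):
        sol = solve_ivp(rhs, (0.0, 1.0), [1.0, cd0], rtol=1e-10, atol=1e-12)
        return sol.y[0, -1], sol.y[1, -1]

    _, cd_end_a = shoot(0.0)
    _, cd_end_b = shoot(1.0)
    # choose cd0 so that the dialysate inlet (z=1) is fresh: Cd(1) = 0
    cd0 = -cd_end_a / (cd_end_b - cd_end_a)
    cb_end, _ = shoot(cd0)
    return Qw * (1.0 - cb_end)
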