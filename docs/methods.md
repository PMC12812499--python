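# Methods

## Model

One solute (urea or creatinine) is tracked as masses in two pools over a
periodic 10 080-minute week. The proximal pool (fraction *f* of the total
distribution volume V_d) is the sampled, directly cleared compartment; the
distal pool (fraction 1 − *f*) receives generation G and feeds the proximal
pool through an intercompartmental clearance K_C. With concentrations C₁,
C₂ expressed per mL of water:

```
d(M₁)/dt = K_C (C₂ − C₁) − K(t) C₁          M₁ = C₁ · f V(t)
d(M₂)/dt = G − K_C (C₂ − C₁)                M₂ = C₂ · (1 − f) V(t)
```

K(t) is the total water clearance acting on the proximal pool: the
residual kidney clearance K_r and extrarenal clearance K_e at all times,
plus the dialyzer clearance K_d during sessions. Ingested fluid carries no
solute and convective dialyzer removal is accounted inside K_d (see below),
so weekly generation exactly balances the clearance integrals at steady
state — a property the tests verify to 0.1%.

**Volume.** V(t) is piecewise linear: it falls by the session's
ultrafiltration volume during each treatment and rises at one constant
drinking rate spread over all interdialytic minutes, closing the weekly
balance exactly. Both pools share volume change in proportion to their
fractions. V_d is anchored as the *postdialysis* volume at the end of the
modeled session. A guard rejects prescriptions that drive V below 5% of
V_d.

**Dialyzer clearance.** In-vitro K₀A urea is derated in vivo by 0.537
(urea) or 0.360 (creatinine, which also absorbs its lower membrane
permeability). The Michaels counter-current expression

```
K_d = Q_w (e^N − 1)/(e^N − Q_w/Q_d),   N = K₀A (Q_d − Q_w)/(Q_w Q_d)
```

is evaluated on the solute's carrier flow: blood water
Q_b (0.72 Hct + 0.93 (1 − Hct)) for urea, plasma water 0.93 Q_b (1 − Hct)
for creatinine (no red-cell equilibration within a pass). Ultrafiltration
at rate Q_uf (session UF volume over duration, constant) adds
Q_uf (1 − K_d/Q_w) — filtered fluid can only remove solute not already
extracted diffusively. This additive-transmittance form is the standard
convention; the matched-flow limit K_d = Q_w K₀A/(K₀A + Q_w) is handled
explicitly.

**Units.** Internal concentrations are mg/mL of water. Plasma
concentrations (mg/dL) are C_water × (1 − f_p) × 100 with plasma protein
volume fraction f_p = 0.07 by default, and water clearances convert to
plasma clearances by 1/(1 − f_p) ≈ 1.075. Exact algebraic inverses are used
throughout rather than the rounded 1.075, keeping round trips lossless; the
difference is 0.025%.

## Integration and steady state

Within each minute the coefficients (volumes at the minute midpoint,
clearances) are frozen, making the system linear with constant
coefficients; the update is the exact matrix exponential of the 2×2
compartmental matrix, computed in closed form from its (always real)
eigenvalues, with a Taylor fallback at the measure-zero degenerate point
Q ≈ 0. The stepping is therefore exact per minute up to the
frozen-coefficient approximation and unconditionally stable, including the
stiff large-K_C regime used to verify the single-pool limit.

The 10 080 per-minute affine updates are composed once into a weekly map
x → A x + b; the periodic steady state is obtained by fixed-point iteration
of that map (initialized at the well-mixed estimate G·10080/∫K dt) to
1e-6 mg/mL on the start-of-week concentrations, capped at 200 weeks. A
model with generation but no clearance anywhere has no steady state and
raises after the cap. Verified accuracy of the minute stepping against a
brute-force 1-second Euler integrator is < 0.5% over a full week.

Pre/post-dialysis samples are the proximal concentration at the session's
start/end minute (half-open `[start, start + duration)` convention, week
origin Monday 00:00). The time-averaged concentration over a urine window
is the arithmetic mean of C₁ over its minutes, wrapping the week boundary
when needed.

## Solvers

*Clearance mode.* The steady-state predialysis value is strictly
decreasing in K_r, so the measured value pins a unique clearance. Brent's
method on [0, 40] mL/min (40 is far beyond any dialysis-requiring patient;
configurable) converges in ~10 forward simulations to 1e-4 mL/min, with the
concentration match checked to 0.001 mg/dL. A measurement above the anuric
prediction returns K_r = 0 flagged `converged=False` (inconsistent
GCr/VdCr or lab error); below the bracket-top prediction raises. No
"rough guess" seeding is needed — bracketing plus monotonicity is
sufficient.

*Generation mode.* The model is linear in G, so the weekly profile scales
proportionally with it and the post/pre ratio depends only on VdCr and
K_r. Each outer pass therefore (i) solves VdCr by Brent so the modeled
ratio matches the measured one, (ii) rescales GCr in closed form to match
the measured predialysis value, and (iii) refreshes the urine-based K_r as
excretion rate over the current profile's time-averaged water
concentration. Outer iteration stops when K_r moves < 0.01 mL/min (cap
100); a final polish pass at the converged clearance tightens VdCr
(xtol 1e-5) and GCr so the reported fit reproduces the measurements to
0.001 mg/dL. This is the same fixed point as a fully nested iteration, at a
fraction of the simulations.

## Defaults and tunables

| parameter | default | units | rationale |
|---|---|---|---|
| proximal fraction *f* | 1/3 | — | classic two-pool convention (extracellular-like pool) |
| K_C per kg | 8 | mL/min/kg | literature-typical intercompartmental clearance; configurable |
| K_e creatinine | 0.038 | L/day/kg | small extrarenal (gut) degradation, ≈1.8 mL/min at 70 kg |
| K_e urea | 0 | — | negligible |
| hematocrit | 0.30 | — | typical treated HD patient; configurable per patient |
| plasma protein fraction | 0.07 | — | standard; sets the 0.93/1.075 conversions |
| K_r bracket | [0, 40] | mL/min | upper bound far above dialysis-requiring range |
| steady-state tolerance | 1e-6 | mg/mL | start-of-week concentration change per week |

The intercompartmental multiplier and the exact extrarenal creatinine
clearance are known only as orders of magnitude in the source literature;
both are explicit parameters. The round-trip validation is insensitive to
them because forward and inverse passes share the model.

## Synthetic cohort

The generator emulates a 24-patient incremental-HD study population: half
once-weekly (Monday; in-vitro K₀A urea 800), half twice-weekly
(Monday–Friday or Tuesday–Saturday; K₀A 950), all sessions 240 min at
Q_b 300 / Q_d 500. Truth parameters are truncated normals: GCr 1091 ± 377
mg/day (> 200), VdCr 22.7 ± 2.4 L (> 10), KrCrW 7.43 ± 4.07 mL/min (≥ 0),
UF 0.78 ± 0.79 L (1/wk) and 1.28 ± 0.88 L (2/wk) (≥ 0), ages 70.8 ± 13.2 /
68.0 ± 7.6 y, male fractions 9/12 and 8/12. Weight is derived from sampled
VdCr through a sampled VdCr/weight ratio (0.35 ± 0.076, truncated to
[0.20, 0.55]) so volumes and weights stay mutually consistent; heights
(168 ± 9 cm) matter only for Watson comparisons. Parameters are drawn
independently given weight — real covariances (muscle mass vs clearance
etc.) are not published. Default seed 20251003.

Measurements are generated from each patient's own simulated steady state:
serum values read off the profile with multiplicative lab noise (default
CV 2%), urine as the integral of true K_r × C₁ over the full interdialytic
interval in daily aliquots (the final aliquot exactly the last 24 h) with
per-aliquot collection noise (default CV 5%), urine volume from a plausible
diuresis rate (0.7 ± 0.2 mL/min). With zero noise the pipeline closes
exactly, which is what the recovery tests exploit. What passing on these
data does **not** show: robustness to model misspecification (real patients
violate the two-pool assumptions, have access recirculation, non-constant
intake, assay bias), since the generator and the solvers share the model.

## Numerical choices and limitations

- Week iteration rather than direct solution of (I − A)x = b keeps the
  spec'd diagnostic (`weeks_to_converge`) and identical semantics; the map
  is precomputed so iteration cost is negligible. One forward simulation
  runs in ~40 ms; the full 147-point round-trip grid in ~20 s.
- The frozen-coefficient minute step introduces O(ΔV/V per minute) error,
  bounded by the 1-second-oracle comparison at < 0.5% and in practice ~1e-4.
- Problem sizes used in tests and validation: the full 147-point grid, a
  20-draw mass-balance sweep, and cohorts of 4–40 synthetic patients —
  chosen to exercise every schedule and parameter regime the model admits.
- Degenerate inputs: empty schedules are allowed (continuous-clearance
  closed forms); zero clearance with positive generation raises a
  convergence error; overlapping sessions, non-positive flows/volumes and
  out-of-range fractions are rejected at construction.
- Not modeled: access/cardiopulmonary recirculation, intradialytic refill
  physiology, rebound sampling delay for the post value, phosphate
  kinetics, hemodiafiltration, equilibrated Kt/V. The urine/urea-clearance
  average sometimes used for "GFR" is not a headline output.
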