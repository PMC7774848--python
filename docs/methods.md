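# Methods

This note documents the models behind `batbaro`, the parameters that matter,
the numerical choices, and what the synthetic inputs do and do not represent.

## Scope and framing

The question is whether a bat flying near an operating utility-scale turbine
can encounter pressure changes fast and deep enough to cause barotrauma.
Everything is computed for the open 5-MW reference machine (63 m rotor
radius, three blades) at 5, 7.5 and 10 m/s wind — the span of wind speeds in
which bats are observed to fly, with 10 m/s the worst case.  Two mechanisms
are modeled: the low/high-pressure lobes hugging the blade's leading edge,
and the low-pressure core of the blade-tip vortex.  The analysis is
deliberately 2-D and steady: the 90%-span section is where blade speed is
near maximal while tip relief is still small, so it bounds what any blade
section can do.

## Rotor aerodynamics (BEM)

Classical blade-element momentum theory with:

* Prandtl tip and hub loss factors `F = (2/π) acos(e^{-f})`,
  `f = B(R−r)/(2r sinφ)` (hub analog with `r−R_hub`);
* the Buhl high-induction relation replacing the momentum branch when the
  local thrust coefficient exceeds `0.96 F`;
* fixed-point iteration on `(a, a')`, under-relaxation 0.3, residual
  tolerance 1e-8, at most 500 iterations, no randomness.  Non-convergence
  raises with the residual history (never observed on the bundled inputs).

Bound circulation per station is `Γ = L'/(ρv) = ½ c C_l v`; the code carries
both algebraic routes and the tests require them to agree to 1e-10.  The
tip-vortex strength is the spanwise maximum of `Γ(r_b)` — the standard
potential-flow roll-up argument.  On the bundled rotor this gives
`Γ_vortex ≈ 35 / 55 / 74 m²/s` at 5 / 7.5 / 10 m/s, peaking around 80% span.

The published aeroelastic operating table is treated as authoritative for
the *section state* driving the pressure field (relative speed 45.3 / 52.5 /
68.7 m/s and angle of attack 7.2 / 9.1 / 9.2° at 90% span): a standard BEM
with the public twist schedule reproduces the relative speeds to well under
1% but yields smaller angles of attack (~4.5–5.6°), and the original study's
aeroelastic configuration is not public.  BEM therefore supplies inductions
and circulation; the tabulated `(u_rel, α)` drive the panel stage.

## Tip vortex

Vatistas swirl law with exponent n = 2 — the member of the family whose
radial momentum integral matches the closed-form pressure profile used here;
a quadrature oracle (`batbaro.validation`) integrates `dp/dr = ρv_θ²/r`
numerically and agrees with the closed form to ~1e-16 relative, which pins
the exponent.  Core radius from the experimental correlation
`r_c = 0.05 c̄ = 0.171 m` for the bundled planform.  Viscous core growth and
turbulent decay downstream are real and reduce the deficit rapidly (doubling
`r_c` removes 75% of it); they are exposed only as the `core_growth ≥ 1`
multiplier (default 1), so the reported center pressures are conservative
upper bounds on magnitude, consistent with the source analysis.

## Blade-section pressure field

A Hess–Smith panel method (constant source per panel, one shared vortex
strength, Kutta closure via equal-and-opposite tangential velocities on the
trailing-edge panels) replaces RANS CFD.  Influence integrals use the
complex-log form of the constant source/vortex panel; collocation-point
self-terms take the exterior-side limit explicitly.  ~200 panels with cosine
clustering; the linear solve is the only numerics.

Validation is analytic rather than experimental: the solver reproduces the
exact conformal-map solution of a Kármán–Trefftz airfoil (the Joukowski
family generalized to a finite trailing-edge angle; at the cusped Joukowski
limit any low-order discrete Kutta closure degenerates to first-order
convergence, so the 18° member is used) to 0.3% RMS in surface speed at 240
panels, and matches the thin-airfoil lift slope within 10%.

Known, documented bias: an inviscid method over-predicts the suction peak at
high angle of attack (no viscous decambering).  Near-surface minima at the
10 m/s state run ~20% deeper than the reference RANS-derived values; all
comparisons against those values are therefore tolerance bands (±30%), not
exact targets.  Compressibility is ignored (tip Mach ≈ 0.2, <3%
dynamic-pressure error).

The 90%-span profile itself is not published beyond "64-series, 17% thick";
the bundled section is a generated 17%-thick NACA 4-digit-law shape with 3%
camber at mid-chord (design lift ≈ 0.6, like the public reference section),
marked `_synthetic`.  The true 6-series nose is slightly sharper, which
would deepen the inviscid peak; the 4-digit stand-in is the softer, more
RANS-like choice.

## Flight paths and exposure

Section-frame kinematics: the relative wind `u_rel` meets the chord at `α`;
the rotor-axis (downwind) direction makes the blade-setting angle
(twist + pitch ≈ 0.9°) with the section normal.  A bat flying at signed
speed `s` with respect to the wind adds `s` along the rotor axis, so its
blade-frame velocity is `u_rel(cos α, sin α) + s·n̂`.  Positive `s` (with
the wind) crosses from upwind; the canonical suite uses s ∈ {0, ±5, ±10}
m/s and the published-table extrema are realized at |s| = 10.

Tracking is ballistic by default: straight lines in the blade frame.  The
retained force model treats the bat as a *trimmed passive particle* —
bluff-body drag (C_d = 0.47) on the sphere-equivalent body cross-section
(~10 cm² for 25 g at unit density), measured relative to the trimmed
far-field state.  Wing area (0.0117 m²) and lift coefficient (1.0) describe
the trim state but are deliberately not slaved to instantaneous slip: a
quasi-steady wing model would deflect paths by ~0.1 m through the rotor's
induced far field, which is a statement about active flight control, not
about the blade's transient.  Under the passive model, deflection during the
approach into the leading-edge pressure peak is sub-millimeter and the
sampled pressure extreme changes by <3%, which is the operative sense in
which aerodynamic forces are negligible and the ballistic default is valid.

Path families: per blade side, six paths spaced 20 mm apart; the closest is
found by bisection on the lateral offset until it clears the surface by less
than 1 mm (tolerance 0.1 mm), the farthest sits ~100 mm out.  Strike
detection intersects the path polyline with the section contour (tolerance
1e-6 m).  Time step `Δt = chord/(400 u_rel)` (~8.4e-5 s at 10 m/s); halving
it moves the metrics by <1%.  No randomness anywhere in the pipeline.

Exposure metrics are measured against the ambient band
`|p − p∞| ≤ band_fraction · p∞`, with `band_fraction = 0.05` (±5066 Pa) — the
literal "within 5% of atmospheric" reading; the fraction is configurable.
`t_rise` runs from the last in-band sample to the global extreme,
`t_recover` from the extreme to the last out-of-band sample, and
`t_outside_band` sums every out-of-band interval.  At 10 m/s wind the
grazing low-pressure path exceeds the band for ~8 ms in total; at 5 and
7.5 m/s the excursions never leave the ±5% band at all.

## Thresholds and ratios

The low-pressure reference is the rodent rapid-decompression dataset:
exposures between −45.5 and −86.5 kPa for 0.0021–1.9 s, no mortality below a
58 kPa drop, first mortality at 58.6 kPa (rats, 168 g mean body mass — the
variant figure of 186 g that appears once in the source is recorded but not
used).  The high-pressure reference is the mouse blast LD50 (184 kPa at
20.7 g, the mammal closest to bat mass with data).  Safety ratios are
`|threshold| / |predicted|`, rounded half-away-from-zero when an integer
factor is quoted.  The tip-vortex comparison is labelled against the
*rodent* low-pressure threshold (the source's conclusion attributes it to
mice; the underlying 58.6 kPa number is from rats).  An allometric log-log
LD50 fit is provided as an exploratory tool only; no published regression
coefficients exist to validate it against, so no cross-species mortality
claim is derived from it.

## Synthetic inputs

* **Planform** — the 17 aerodynamic stations of the public reference blade
  (transcribed radii, chords, twists, airfoil families).  It reproduces the
  two printed geometric anchors: mean chord → `r_c = 0.171 m`, 90%-span
  chord 2.313 m.
* **Polars** — generated by a parametric model: genuinely linear lift
  `slope·sin(α−α₀)` capped at `C_l,max` below stall, cosine-blended to a
  flat-plate deep-stall curve over 15° beyond it, `C_d = C_d0 + k C_l²`
  attached.  Per-family parameters (zero-lift angle, slope, `C_l,max`,
  stall angle, `C_d0`) are fixed from the published characteristics of the
  reference blade's airfoil families; root cylinders are drag-only (0.50 /
  0.35).  These are stand-ins for the full tabulated reference polars: they
  reproduce the attached-flow regime the rotor operates in, not post-stall
  hysteresis or Reynolds trends.
* **Section shape** — see above; synthetic 64-series-like.
* **Threshold tables** — the printed constraints are honored exactly; the
  per-record outcome percentages (available only as a figure in the source)
  are invented, so only the onset value and ranges are meaningful.  A seeded
  generator (`synthetic_threshold_tables`) produces randomized variants for
  property tests.

Because the polars and section are parametric stand-ins, agreement with the
reference values is expected at the few-percent level for circulation-driven
quantities (the 10 m/s vortex center pressure lands within 0.2%) and only at
the tens-of-percent level for inviscid near-surface extrema — which is how
the test suite weights them.  Passing tests demonstrate the pipeline's
internal consistency and its agreement with the published anchors under
these stand-ins; they do not certify the absolute accuracy of any individual
polar or profile.

## Problem sizes and determinism

Defaults: 17 blade stations, 200 panels, ~3000 samples per path, 12 paths
per wind speed and flight condition, three wind speeds.  The full pipeline
is a few tens of seconds on one core; every stage is deterministic, so
repeated runs produce byte-identical CSV/JSON outputs (floats serialized at
6 significant digits).

## Known limitations

3-D rotor CFD, unsteady aerodynamics, dynamic stall, vortex aging/advection,
rotor-plane crossing statistics, strike probability and any physiological
modelling of bat airways are all out of scope.  The comparison rests on the
assumption — unavoidable, given that no bat decompression data exist — that
bat tissue responds to rapid pressure change like that of other small
mammals.
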