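# batbaro

Can the pressure transients around a utility-scale wind-turbine blade and its
tip vortex plausibly cause barotrauma in bats?  `batbaro` is a desk-scale
analysis pipeline that answers this quantitatively for the open 5-MW
reference turbine: it computes the pressure fields a flying bat can actually
reach, extracts exposure magnitudes and durations along grazing flight paths,
and compares them with published mammalian pressure-mortality thresholds.

It is written for researchers in wind-energy/wildlife interaction and
quantitative conservation who want a reproducible, fully open implementation
of this argument — no commercial CFD or aeroelastic codes required.

## The model chain

1. **Blade-element momentum (BEM).**  For wind speed `u∞` and tip-speed ratio
   `λ`, the induction factors `(a, a')` at each blade station solve the
   momentum/blade-element balance with Prandtl tip/hub losses and the Glauert
   (Buhl) high-induction correction.  Lift per unit span maps to bound
   circulation by Kutta–Joukowski, `Γ(r_b) = L'(r_b)/(ρ v(r_b)) = ½ c C_l v`.
2. **Tip vortex.**  The vortex strength is the spanwise circulation maximum,
   `Γ_vortex = max_r Γ(r_b)`; the core radius follows the experimental
   correlation `r_c = 0.05 c̄` (0.17 m here).  The Vatistas `n = 2` swirl law

       v_θ(r̄) = Γ/(2π r_c) · r̄ / √(1 + r̄⁴),   r̄ = r/r_c

   integrates the radial momentum balance `dp/dr = ρ v_θ²/r` exactly to

       p(r) − p∞ = ρΓ²/(8π² r_c²) · [atan(r²/r_c²) − π/2]

   with its minimum `−ρΓ²/(16π r_c²)` at the center.
3. **Blade-section field.**  The 90%-span section (chord 2.31 m, 17% thick)
   is solved with a Hess–Smith panel method at the published section state
   (`u_rel`, `α` per wind speed); pressures follow Bernoulli,
   `C_p = (p − p∞)/(½ρu_rel²) = 1 − (v/u_rel)²`.
4. **Flight exposure.**  Bats are ballistic particles in the blade frame
   (aerodynamic forces on a 25 g body are negligible over the ~0.03 s blade
   passage — the package quantifies this).  Families of six paths per blade
   side, 20 mm apart, with the closest grazing the surface at <1 mm, give
   pressure–time traces; exposure is the time spent outside ±5% of
   atmospheric pressure.
5. **Thresholds.**  Predicted exposures are divided into the rodent
   rapid-decompression mortality onset (58.6 kPa below ambient) and the mouse
   blast LD50 (184 kPa) to give safety factors.

## Worked example

```python
from batbaro import (reference_fixture_set, operating_point_for, mean_chord,
                     spanwise_circulation, tip_vortex_strength,
                     TipVortex, core_radius, vortex_pressure)

fx = reference_fixture_set()
op = operating_point_for(10.0)                      # 10 m/s wind, TSR 7.6
dist = spanwise_circulation(fx.planform, op, fx.polars)
gamma = tip_vortex_strength(dist)                   # 73.9 m^2/s
r_c = core_radius(mean_chord(fx.planform))          # 0.1709 m
tv = TipVortex(gamma, r_c, op.rho)
print(vortex_pressure(0.0, tv, op.p_inf) - op.p_inf)  # -4561.975712312662
```

The vortex core at the highest wind speed bats fly in sits ~4.6 kPa below
atmospheric — about 13 times smaller than the smallest pressure drop known to
kill a rat.  The full pipeline:

```sh
batbaro run --output scratch/run
```

prints the per-wind-speed summary (pressures in Pa relative to atmospheric):

```
 u_inf_mps  dp_min_path_1mm_Pa  dp_min_path_100mm_Pa  dp_min_vortex_Pa  dp_max_path_1mm_Pa  dp_max_path_100mm_Pa
       5.0             -2934.6               -1976.7           -1024.3              1117.3                 836.5
       7.5             -4975.0               -3223.9           -2555.6              1526.2                1211.8
      10.0             -8330.4               -5551.4           -4562.0              2499.6                2007.0
```

Rows are wind speeds; columns give the minimum pressure along the closest
(<1 mm) and farthest (~100 mm) low-pressure-side paths, the vortex-center
minimum, and the corresponding maxima on the high-pressure side.  Magnitudes
grow roughly with the square of the blade speed, and a bat 100 mm away
already sees a third less than one grazing the surface.  `batbaro validate`
runs the analytic oracle suite (vortex quadrature, conformal-map panel
comparison, Betz bound); `batbaro report` recomputes threshold ratios from a
saved summary.

The numbered drivers under `analysis/` rebuild each stage's tables in
`results/`: operating conditions, spanwise circulation and vortex profiles,
surface pressures and their wall-distance decay, flight-path exposure, and
the threshold comparison.

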