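Fixture provenance
==================
nrel5mw_planform.csv
    17 aerodynamic blade stations of the open 5-MW reference turbine
    (radii, chords, twists and airfoil families of the public definition,
    transcribed).  Root-cylinder thickness ratios stored as 0.99; the
    outboard airfoil thickness follows the 17% figure used by the analysis.
polar_*_synthetic.csv
    SYNTHETIC lift/drag polars generated by batbaro.bem.make_polar_table
    (linear lift blended to a flat-plate deep-stall curve) with per-family
    parameters fixed from the published characteristics of the reference
    blade's airfoil families.  They are stand-ins for the full tabulated
    reference polars, which are not bundled.
naca64ish_17pct_synthetic.dat
    SYNTHETIC 17%-thick, 3%-camber section built from NACA 4-digit laws as a
    stand-in for the (unspecified) 64-series profile at 90% span.
rodent_decompression_synthetic.csv
    SYNTHETIC rapid-decompression outcome table constrained by the published
    rat/rabbit study: exposures within [-86.5, -45.5] kPa, durations within
    [0.0021, 1.9] s, no mortality below a 58 kPa drop, first mortality at
    58.6 kPa, rat body mass 168 g.  Per-record percentages are invented.
blast_ld50.csv
    The published mouse blast-overpressure LD50 point (20.7 g, 184 kPa).
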