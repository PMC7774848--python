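# 5-MW reference turbine blade: 17 aerodynamic stations
# rotor_radius_m: 63.0
# hub_radius_m: 1.5
# n_blades: 3
r_b_m,chord_m,twist_deg,airfoil_id,thickness_ratio
2.8667,3.542,13.308,cylinder1,0.99
5.6,3.854,13.308,cylinder1,0.99
8.3333,4.167,13.308,cylinder2,0.99
11.75,4.557,13.308,du40_a17,0.405
15.85,4.652,11.48,du35_a17,0.35
19.95,4.458,10.162,du35_a17,0.35
24.05,4.249,9.011,du30_a17,0.3
28.15,4.007,7.795,du25_a17,0.25
32.25,3.748,6.544,du25_a17,0.25
36.35,3.502,5.361,du21_a17,0.21
40.45,3.256,4.188,du21_a17,0.21
44.55,3.01,3.125,naca64_a17,0.17
48.65,2.764,2.319,naca64_a17,0.17
52.75,2.518,1.526,naca64_a17,0.17
56.1667,2.313,0.863,naca64_a17,0.17
58.9,2.086,0.37,naca64_a17,0.17
61.6333,1.419,0.106,naca64_a17,0.17
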