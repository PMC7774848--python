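alpha_deg,cl,cd
-180,1.59204e-16,0.008
-175,0.112871,0.017875
-170,0.222313,0.0471998
-165,0.325,0.0950835
-160,0.417812,0.160071
-155,0.497929,0.240188
-150,0.562917,0.333
-145,0.6108,0.435687
-140,0.640125,0.545129
-135,0.65,0.658
-130,0.640125,0.770871
-125,0.6108,0.880313
-120,0.562917,0.983
-115,0.497929,1.07581
-110,0.417812,1.15593
-105,0.325,1.22092
-100,0.222313,1.2688
-95,0.112871,1.29813
-90,-7.9602e-17,1.308
-85,-0.112871,1.29813
-80,-0.222313,1.2688
-75,-0.325,1.22092
-70,-0.417812,1.15593
-65,-0.497929,1.07581
-60,-0.562917,0.983
-55,-0.6108,0.880313
-50,-0.640125,0.770871
-45,-0.65,0.658
-40,-0.640125,0.545129
-35,-0.6108,0.435687
-30,-0.594064,0.322032
-29.5,-0.60796,0.306007
-29,-0.626314,0.289081
-28.5,-0.648963,0.27147
-28,-0.675697,0.253392
-27.5,-0.706257,0.235061
-27,-0.740341,0.216682
-26.5,-0.777604,0.198453
-26,-0.817659,0.180559
-25.5,-0.860084,0.16317
-25,-0.904424,0.146439
-24.5,-0.950192,0.130505
-24,-0.99688,0.115484
-23.5,-1.04396,0.101474
-23,-1.09088,0.0885532
-22.5,-1.1371,0.0767779
-22,-1.18206,0.066185
-21.5,-1.2252,0.0567914
-21,-1.26598,0.0485951
-20.5,-1.30387,0.0415761
-20,-1.33837,0.0356976
-19.5,-1.36898,0.030908
-19,-1.39526,0.0271423
-18.5,-1.4168,0.0243239
-18,-1.43322,0.0223669
-17.5,-1.44422,0.0211779
-17,-1.41531,0.02007
-16.5,-1.36305,0.0191474
-16,-1.31021,0.0183
-15.5,-1.25728,0.0174845
-15,-1.20425,0.0167014
-14.5,-1.15113,0.0159506
-14,-1.09793,0.0152326
-13.5,-1.04463,0.0145476
-13,-0.991263,0.0138956
-12.5,-0.937817,0.013277
-12,-0.884299,0.0126919
-11.5,-0.830714,0.0121405
-11,-0.777066,0.011623
-10.5,-0.723359,0.0111395
-10,-0.669596,0.0106902
-9.5,-0.615782,0.0102751
-9,-0.561922,0.00989454
-8.5,-0.508019,0.0095485
-8,-0.454077,0.00923711
-7.5,-0.4001,0.00896048
-7,-0.346093,0.00871868
-6.5,-0.29206,0.00851179
-6,-0.238004,0.00833988
-5.5,-0.183931,0.00820298
-5,-0.129843,0.00810116
-4.5,-0.0757454,0.00803442
-4,-0.021642,0.00800281
-3.5,0.032463,0.00800632
-3,0.0865655,0.00804496
-2.5,0.140661,0.00811871
-2,0.194747,0.00822756
-1.5,0.248817,0.00837146
-1,0.302869,0.00855038
-0.5,0.356897,0.00876425
0,0.410898,0.00901302
0.5,0.464868,0.00929661
1,0.518803,0.00961494
1.5,0.572698,0.0099679
2,0.626549,0.0103554
2.5,0.680353,0.0107773
3,0.734105,0.0112335
3.5,0.787801,0.0117238
4,0.841437,0.0122481
4.5,0.895008,0.0128062
5,0.948512,0.0133981
5.5,1.00194,0.0140233
6,1.0553,0.0146819
6.5,1.10857,0.0153736
7,1.16176,0.0160982
7.5,1.21487,0.0168554
8,1.26788,0.0176451
8.5,1.32079,0.0184669
9,1.3736,0.0193207
9.5,1.42511,0.020229
10,1.4414,0.0208011
10.5,1.42758,0.0211778
11,1.40764,0.0218339
11.5,1.38195,0.0228373
12,1.35095,0.0242557
12.5,1.31514,0.0261554
13,1.27505,0.0285993
13.5,1.23123,0.0316454
14,1.1843,0.0353453
14.5,1.13487,0.0397424
15,1.08357,0.0448704
15.5,1.03106,0.0507524
16,0.977975,0.0573991
16.5,0.924955,0.0648081
17,0.872626,0.0729631
17.5,0.821593,0.0818331
18,0.772435,0.0913725
18.5,0.725701,0.10152
19,0.681901,0.112201
19.5,0.641505,0.123325
20,0.604935,0.134789
20.5,0.572566,0.146478
21,0.544718,0.158263
21.5,0.521657,0.17001
22,0.503592,0.181574
22.5,0.490677,0.192806
23,0.483003,0.203553
23.5,0.480608,0.21366
24,0.483468,0.222976
24.5,0.490561,0.231562
25,0.497929,0.240188
25.5,0.505145,0.248942
26,0.512207,0.25782
26.5,0.519113,0.26682
27,0.525861,0.27594
27.5,0.532449,0.285175
28,0.538874,0.294525
28.5,0.545136,0.303985
29,0.551231,0.313552
29.5,0.557159,0.323225
30,0.562917,0.333
35,0.6108,0.435687
40,0.640125,0.545129
45,0.65,0.658
50,0.640125,0.770871
55,0.6108,0.880313
60,0.562917,0.983
65,0.497929,1.07581
70,0.417812,1.15593
75,0.325,1.22092
80,0.222313,1.2688
85,0.112871,1.29813
90,7.9602e-17,1.308
95,-0.112871,1.29813
100,-0.222313,1.2688
105,-0.325,1.22092
110,-0.417812,1.15593
115,-0.497929,1.07581
120,-0.562917,0.983
125,-0.6108,0.880313
130,-0.640125,0.770871
135,-0.65,0.658
140,-0.640125,0.545129
145,-0.6108,0.435687
150,-0.562917,0.333
155,-0.497929,0.240188
160,-0.417812,0.160071
165,-0.325,0.0950835
170,-0.222313,0.0471998
175,-0.112871,0.017875
180,-1.59204e-16,0.008
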