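alpha_deg,cl,cd
-180,1.59204e-16,0.009
-175,0.112871,0.018875
-170,0.222313,0.0481998
-165,0.325,0.0960835
-160,0.417812,0.161071
-155,0.497929,0.241188
-150,0.562917,0.334
-145,0.6108,0.436687
-140,0.640125,0.546129
-135,0.65,0.659
-130,0.640125,0.771871
-125,0.6108,0.881313
-120,0.562917,0.984
-115,0.497929,1.07681
-110,0.417812,1.15693
-105,0.325,1.22192
-100,0.222313,1.2698
-95,0.112871,1.29913
-90,-7.9602e-17,1.309
-85,-0.112871,1.29913
-80,-0.222313,1.2698
-75,-0.325,1.22192
-70,-0.417812,1.15693
-65,-0.497929,1.07681
-60,-0.562917,0.984
-55,-0.6108,0.881313
-50,-0.640125,0.771871
-45,-0.65,0.659
-40,-0.640125,0.546129
-35,-0.6108,0.436687
-30,-0.598746,0.321816
-29.5,-0.614233,0.305542
-29,-0.634287,0.288404
-28.5,-0.658724,0.270619
-28,-0.687315,0.252405
-27.5,-0.71978,0.233976
-27,-0.755796,0.215537
-26.5,-0.794994,0.197284
-26,-0.836966,0.179399
-25.5,-0.881268,0.162051
-25,-0.927421,0.145392
-24.5,-0.97492,0.129555
-24,-1.02323,0.114656
-23.5,-1.07181,0.100787
-23,-1.1201,0.0880241
-22.5,-1.16752,0.0764202
-22,-1.2135,0.0660085
-21.5,-1.25748,0.0568025
-21,-1.2989,0.0487967
-20.5,-1.33723,0.0419679
-20,-1.37194,0.0362763
-19.5,-1.40255,0.0316676
-19,-1.42862,0.0280741
-18.5,-1.44972,0.0254171
-18,-1.4655,0.0236087
-17.5,-1.47563,0.022554
-17,-1.45776,0.0217633
-16.5,-1.40524,0.0208482
-16,-1.35249,0.0199753
-15.5,-1.29964,0.0191343
-15,-1.24668,0.0183253
-14.5,-1.19364,0.0175486
-14,-1.1405,0.0168044
-13.5,-1.08727,0.016093
-13,-1.03397,0.0154145
-12.5,-0.98058,0.0147692
-12,-0.927119,0.0141573
-11.5,-0.873588,0.0135789
-11,-0.81999,0.0130343
-10.5,-0.766329,0.0125236
-10,-0.71261,0.0120469
-9.5,-0.658837,0.0116044
-9,-0.605014,0.0111963
-8.5,-0.551145,0.0108226
-8,-0.497233,0.0104834
-7.5,-0.443284,0.010179
-7,-0.389301,0.00990933
-6.5,-0.335289,0.00967451
-6,-0.281251,0.00947461
-5.5,-0.227191,0.00930969
-5,-0.173114,0.00917981
-4.5,-0.119024,0.009085
-4,-0.0649251,0.00902529
-3.5,-0.010821,0.0090007
-3,0.0432838,0.00901124
-2.5,0.0973854,0.0090569
-2,0.15148,0.00913768
-1.5,0.205562,0.00925353
-1,0.259629,0.00940444
-0.5,0.313676,0.00959036
0,0.3677,0.00981122
0.5,0.421695,0.010067
1,0.475658,0.0103575
1.5,0.529585,0.0106828
2,0.583472,0.0110426
2.5,0.637314,0.011437
3,0.691107,0.0118658
3.5,0.744848,0.0123288
4,0.798533,0.0128259
4.5,0.852156,0.013357
5,0.905715,0.0139219
5.5,0.959204,0.0145204
6,1.01262,0.0151524
6.5,1.06596,0.0158176
7,1.11922,0.0165159
7.5,1.17239,0.017247
8,1.22548,0.0180107
8.5,1.27847,0.0188069
9,1.33136,0.0196351
9.5,1.38415,0.0204952
10,1.43684,0.021387
10.5,1.47781,0.0221951
11,1.46905,0.0224452
11.5,1.45384,0.0229646
12,1.43251,0.0238244
12.5,1.40546,0.025096
13,1.37313,0.0268499
13.5,1.33603,0.0291535
14,1.2947,0.03207
14.5,1.2497,0.0356562
15,1.20166,0.0399612
15.5,1.15119,0.0450248
16,1.09895,0.0508757
16.5,1.04557,0.0575309
17,0.991707,0.0649937
17.5,0.938006,0.0732535
18,0.885094,0.0822847
18.5,0.833578,0.0920462
19,0.784039,0.102482
19.5,0.737026,0.113519
20,0.693049,0.125071
20.5,0.652578,0.137037
21,0.616034,0.149302
21.5,0.583788,0.161737
22,0.55616,0.174207
22.5,0.533411,0.186563
23,0.515749,0.198653
23.5,0.50332,0.210318
24,0.496214,0.221398
24.5,0.494462,0.231732
25,0.498037,0.241164
25.5,0.505145,0.249942
26,0.512207,0.25882
26.5,0.519113,0.26782
27,0.525861,0.27694
27.5,0.532449,0.286175
28,0.538874,0.295525
28.5,0.545136,0.304985
29,0.551231,0.314552
29.5,0.557159,0.324225
30,0.562917,0.334
35,0.6108,0.436687
40,0.640125,0.546129
45,0.65,0.659
50,0.640125,0.771871
55,0.6108,0.881313
60,0.562917,0.984
65,0.497929,1.07681
70,0.417812,1.15693
75,0.325,1.22192
80,0.222313,1.2698
85,0.112871,1.29913
90,7.9602e-17,1.309
95,-0.112871,1.29913
100,-0.222313,1.2698
105,-0.325,1.22192
110,-0.417812,1.15693
115,-0.497929,1.07681
120,-0.562917,0.984
125,-0.6108,0.881313
130,-0.640125,0.771871
135,-0.65,0.659
140,-0.640125,0.546129
145,-0.6108,0.436687
150,-0.562917,0.334
155,-0.497929,0.241188
160,-0.417812,0.161071
165,-0.325,0.0960835
170,-0.222313,0.0481998
175,-0.112871,0.018875
180,-1.59204e-16,0.009
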