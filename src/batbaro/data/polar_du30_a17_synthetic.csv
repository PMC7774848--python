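alpha_deg,cl,cd
-180,1.59204e-16,0.011
-175,0.112871,0.020875
-170,0.222313,0.0501998
-165,0.325,0.0980835
-160,0.417812,0.163071
-155,0.497929,0.243188
-150,0.562917,0.336
-145,0.6108,0.438687
-140,0.640125,0.548129
-135,0.65,0.661
-130,0.640125,0.773871
-125,0.6108,0.883313
-120,0.562917,0.986
-115,0.497929,1.07881
-110,0.417812,1.15893
-105,0.325,1.22392
-100,0.222313,1.2718
-95,0.112871,1.30113
-90,-7.9602e-17,1.311
-85,-0.112871,1.30113
-80,-0.222313,1.2718
-75,-0.325,1.22392
-70,-0.417812,1.15893
-65,-0.497929,1.07881
-60,-0.562917,0.986
-55,-0.6108,0.883313
-50,-0.640125,0.773871
-45,-0.65,0.661
-40,-0.640125,0.548129
-35,-0.6108,0.438687
-30,-0.607509,0.321177
-29.5,-0.625343,0.304405
-29,-0.647754,0.286841
-28.5,-0.674535,0.268704
-28,-0.705428,0.250212
-27.5,-0.740127,0.231579
-27,-0.778283,0.213008
-26.5,-0.819502,0.194693
-26,-0.863352,0.176812
-25.5,-0.909364,0.15953
-25,-0.957039,0.142994
-24.5,-1.00585,0.127331
-24,-1.05525,0.112651
-23.5,-1.10468,0.0990417
-23,-1.15355,0.0865705
-22.5,-1.2013,0.0752842
-22,-1.24733,0.0652096
-21.5,-1.29109,0.0563535
-21,-1.33201,0.048704
-20.5,-1.36956,0.0422319
-20,-1.40322,0.0368918
-19.5,-1.43253,0.0326239
-19,-1.45703,0.0293559
-18.5,-1.47634,0.0270051
-18,-1.4901,0.0254799
-17.5,-1.49802,0.0246825
-17,-1.48941,0.0243101
-16.5,-1.43684,0.023387
-16,-1.38415,0.0224952
-15.5,-1.33136,0.0216351
-15,-1.27847,0.0208069
-14.5,-1.22548,0.0200107
-14,-1.17239,0.019247
-13.5,-1.11922,0.0185159
-13,-1.06596,0.0178176
-12.5,-1.01262,0.0171524
-12,-0.959204,0.0165204
-11.5,-0.905715,0.0159219
-11,-0.852156,0.015357
-10.5,-0.798533,0.0148259
-10,-0.744848,0.0143288
-9.5,-0.691107,0.0138658
-9,-0.637314,0.013437
-8.5,-0.583472,0.0130426
-8,-0.529585,0.0126828
-7.5,-0.475658,0.0123575
-7,-0.421695,0.012067
-6.5,-0.3677,0.0118112
-6,-0.313676,0.0115904
-5.5,-0.259629,0.0114044
-5,-0.205562,0.0112535
-4.5,-0.15148,0.0111377
-4,-0.0973854,0.0110569
-3.5,-0.0432838,0.0110112
-3,0.010821,0.0110007
-2.5,0.0649251,0.0110253
-2,0.119024,0.011085
-1.5,0.173114,0.0111798
-1,0.227191,0.0113097
-0.5,0.281251,0.0114746
0,0.335289,0.0116745
0.5,0.389301,0.0119093
1,0.443284,0.012179
1.5,0.497233,0.0124834
2,0.551145,0.0128226
2.5,0.605014,0.0131963
3,0.658837,0.0136044
3.5,0.71261,0.0140469
4,0.766329,0.0145236
4.5,0.81999,0.0150343
5,0.873588,0.0155789
5.5,0.927119,0.0161573
6,0.98058,0.0167692
6.5,1.03397,0.0174145
7,1.08727,0.018093
7.5,1.1405,0.0188044
8,1.19364,0.0195486
8.5,1.24668,0.0203253
9,1.29964,0.0211343
9.5,1.35249,0.0219753
10,1.40524,0.0228482
10.5,1.45788,0.0237525
11,1.49986,0.0245037
11.5,1.49509,0.0246505
12,1.48368,0.025064
12.5,1.46592,0.0258183
13,1.44218,0.026988
13.5,1.41286,0.0286471
14,1.37844,0.030867
14.5,1.33943,0.0337147
15,1.29638,0.0372513
15.5,1.24989,0.0415301
16,1.20057,0.0465951
16.5,1.14905,0.0524796
17,1.09598,0.0592043
17.5,1.04202,0.066777
18,0.987804,0.0751905
18.5,0.933979,0.0844226
19,0.881168,0.0944355
19.5,0.82997,0.105175
20,0.780958,0.116571
20.5,0.734669,0.128538
21,0.691601,0.140975
21.5,0.652209,0.153767
22,0.6169,0.166785
22.5,0.586028,0.179889
23,0.559896,0.192931
23.5,0.538749,0.205752
24,0.522775,0.21819
24.5,0.512103,0.230079
25,0.506804,0.241251
25.5,0.506889,0.251543
26,0.512207,0.26082
26.5,0.519113,0.26982
27,0.525861,0.27894
27.5,0.532449,0.288175
28,0.538874,0.297525
28.5,0.545136,0.306985
29,0.551231,0.316552
29.5,0.557159,0.326225
30,0.562917,0.336
35,0.6108,0.438687
40,0.640125,0.548129
45,0.65,0.661
50,0.640125,0.773871
55,0.6108,0.883313
60,0.562917,0.986
65,0.497929,1.07881
70,0.417812,1.15893
75,0.325,1.22392
80,0.222313,1.2718
85,0.112871,1.30113
90,7.9602e-17,1.311
95,-0.112871,1.30113
100,-0.222313,1.2718
105,-0.325,1.22392
110,-0.417812,1.15893
115,-0.497929,1.07881
120,-0.562917,0.986
125,-0.6108,0.883313
130,-0.640125,0.773871
135,-0.65,0.661
140,-0.640125,0.548129
145,-0.6108,0.438687
150,-0.562917,0.336
155,-0.497929,0.243188
160,-0.417812,0.163071
165,-0.325,0.0980835
170,-0.222313,0.0501998
175,-0.112871,0.020875
180,-1.59204e-16,0.011
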