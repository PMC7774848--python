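alpha_deg,cl,cd
-180,1.59204e-16,0.017
-175,0.112871,0.026875
-170,0.222313,0.0561998
-165,0.325,0.104083
-160,0.417812,0.169071
-155,0.497929,0.249188
-150,0.562917,0.342
-145,0.6108,0.444687
-140,0.640125,0.554129
-135,0.65,0.667
-130,0.640125,0.779871
-125,0.6108,0.889313
-120,0.562917,0.992
-115,0.497929,1.08481
-110,0.417812,1.16493
-105,0.325,1.22992
-100,0.222313,1.2778
-95,0.112871,1.30713
-90,-7.9602e-17,1.317
-85,-0.112871,1.30713
-80,-0.222313,1.2778
-75,-0.325,1.22992
-70,-0.417812,1.16493
-65,-0.497929,1.08481
-60,-0.562917,0.992
-55,-0.6108,0.889313
-50,-0.640125,0.779871
-45,-0.65,0.667
-40,-0.640125,0.554129
-35,-0.6108,0.444687
-30,-0.639747,0.317825
-29.5,-0.664538,0.299692
-29,-0.693819,0.280989
-28.5,-0.727306,0.261939
-28,-0.764663,0.242761
-27.5,-0.805511,0.223663
-27,-0.849425,0.204842
-26.5,-0.895944,0.18648
-26,-0.944568,0.168747
-25.5,-0.994769,0.15179
-25,-1.04599,0.135742
-24.5,-1.09766,0.120712
-24,-1.14919,0.10679
-23.5,-1.19998,0.0940453
-23,-1.24943,0.0825244
-22.5,-1.29694,0.0722543
-22,-1.34192,0.0632413
-21.5,-1.38381,0.0554727
-21,-1.42205,0.0489181
-20.5,-1.45614,0.0435302
-20,-1.48558,0.0392474
-19.5,-1.50994,0.035995
-19,-1.52882,0.0336875
-18.5,-1.54189,0.0322305
-18,-1.54885,0.0315233
-17.5,-1.55,0.031415
-17,-1.50669,0.0306208
-16.5,-1.45505,0.0297031
-16,-1.4033,0.0288156
-15.5,-1.35145,0.0279584
-15,-1.29949,0.027132
-14.5,-1.24743,0.0263364
-14,-1.19527,0.025572
-13.5,-1.14303,0.0248391
-13,-1.09069,0.0241377
-12.5,-1.03828,0.0234681
-12,-0.985783,0.0228306
-11.5,-0.933214,0.0222253
-11,-0.880573,0.0216525
-10.5,-0.827865,0.0211122
-10,-0.775094,0.0206046
-9.5,-0.722264,0.02013
-9,-0.669379,0.0196884
-8.5,-0.616443,0.01928
-8,-0.563461,0.0189049
-7.5,-0.510435,0.0185633
-7,-0.45737,0.0182551
-6.5,-0.404271,0.0179806
-6,-0.351141,0.0177398
-5.5,-0.297984,0.0175328
-5,-0.244804,0.0173596
-4.5,-0.191606,0.0172203
-4,-0.138393,0.0171149
-3.5,-0.0851693,0.0170435
-3,-0.0319394,0.0170061
-2.5,0.021293,0.0170027
-2,0.0745237,0.0170333
-1.5,0.127749,0.0170979
-1,0.180964,0.0171965
-0.5,0.234166,0.017329
0,0.287349,0.0174954
0.5,0.340511,0.0176957
1,0.393647,0.0179297
1.5,0.446753,0.0181975
2,0.499825,0.0184989
2.5,0.552859,0.0188339
3,0.60585,0.0192023
3.5,0.658796,0.0196041
4,0.711691,0.020039
4.5,0.764533,0.0205071
5,0.817316,0.021008
5.5,0.870036,0.0215418
6,0.922691,0.0221082
6.5,0.975275,0.022707
7,1.02779,0.0233381
7.5,1.08022,0.0240012
8,1.13257,0.0246962
8.5,1.18483,0.0254229
9,1.237,0.0261811
9.5,1.28908,0.0269704
10,1.34106,0.0277907
10.5,1.39294,0.0286417
11,1.44471,0.0295232
11.5,1.49638,0.0304348
12,1.54792,0.0313764
12.5,1.54944,0.0314354
13,1.54321,0.0316905
13.5,1.53029,0.0323014
14,1.51096,0.0333489
14.5,1.48561,0.0349129
15,1.45465,0.0370712
15.5,1.41857,0.0398971
16,1.37789,0.0434576
16.5,1.33318,0.0478123
17,1.28504,0.0530109
17.5,1.2341,0.0590918
18,1.181,0.0660809
18.5,1.1264,0.0739902
19,1.07097,0.0828162
19.5,1.01535,0.0925399
20,0.9602,0.103125
20.5,0.906153,0.11452
21,0.853815,0.126653
21.5,0.803767,0.139439
22,0.756554,0.152775
22.5,0.712682,0.166541
23,0.672611,0.180607
23.5,0.636754,0.194826
24,0.60547,0.209042
24.5,0.579066,0.22309
25,0.55779,0.236797
25.5,0.541832,0.249988
26,0.531322,0.262484
26.5,0.526331,0.274109
27,0.526871,0.284689
27.5,0.532449,0.294175
28,0.538874,0.303525
28.5,0.545136,0.312985
29,0.551231,0.322552
29.5,0.557159,0.332225
30,0.562917,0.342
35,0.6108,0.444687
40,0.640125,0.554129
45,0.65,0.667
50,0.640125,0.779871
55,0.6108,0.889313
60,0.562917,0.992
65,0.497929,1.08481
70,0.417812,1.16493
75,0.325,1.22992
80,0.222313,1.2778
85,0.112871,1.30713
90,7.9602e-17,1.317
95,-0.112871,1.30713
100,-0.222313,1.2778
105,-0.325,1.22992
110,-0.417812,1.16493
115,-0.497929,1.08481
120,-0.562917,0.992
125,-0.6108,0.889313
130,-0.640125,0.779871
135,-0.65,0.667
140,-0.640125,0.554129
145,-0.6108,0.444687
150,-0.562917,0.342
155,-0.497929,0.249188
160,-0.417812,0.169071
165,-0.325,0.104083
170,-0.222313,0.0561998
175,-0.112871,0.026875
180,-1.59204e-16,0.017
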