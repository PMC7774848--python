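alpha_deg,cl,cd
-180,1.59204e-16,0.007
-175,0.112871,0.016875
-170,0.222313,0.0461998
-165,0.325,0.0940835
-160,0.417812,0.159071
-155,0.497929,0.239188
-150,0.562917,0.332
-145,0.6108,0.434687
-140,0.640125,0.544129
-135,0.65,0.657
-130,0.640125,0.769871
-125,0.6108,0.879313
-120,0.562917,0.982
-115,0.497929,1.07481
-110,0.417812,1.15493
-105,0.325,1.21992
-100,0.222313,1.2678
-95,0.112871,1.29713
-90,-7.9602e-17,1.307
-85,-0.112871,1.29713
-80,-0.222313,1.2678
-75,-0.325,1.21992
-70,-0.417812,1.15493
-65,-0.497929,1.07481
-60,-0.562917,0.982
-55,-0.6108,0.879313
-50,-0.640125,0.769871
-45,-0.65,0.657
-40,-0.640125,0.544129
-35,-0.6108,0.434687
-30,-0.590735,0.322204
-29.5,-0.603715,0.306446
-29,-0.621188,0.289751
-28.5,-0.643,0.272337
-28,-0.66895,0.25442
-27.5,-0.69879,0.236214
-27,-0.732225,0.217925
-26.5,-0.768918,0.199751
-26,-0.808491,0.181878
-25.5,-0.850527,0.164479
-25,-0.894577,0.14771
-24.5,-0.940159,0.131711
-24,-0.986768,0.116601
-23.5,-1.03388,0.102482
-23,-1.08095,0.0894331
-22.5,-1.12742,0.0775157
-22,-1.17274,0.0667694
-21.5,-1.21636,0.0572142
-21,-1.25772,0.0488512
-20.5,-1.29629,0.0416633
-20,-1.33156,0.0356167
-19.5,-1.36304,0.0306623
-19,-1.39027,0.0267374
-18.5,-1.41282,0.0237677
-18,-1.43033,0.0216691
-17.5,-1.39609,0.0195559
-17,-1.35047,0.0180573
-16.5,-1.29949,0.017132
-16,-1.24743,0.0163364
-15.5,-1.19527,0.015572
-15,-1.14303,0.0148391
-14.5,-1.09069,0.0141377
-14,-1.03828,0.0134681
-13.5,-0.985783,0.0128306
-13,-0.933214,0.0122253
-12.5,-0.880573,0.0116525
-12,-0.827865,0.0111122
-11.5,-0.775094,0.0106046
-11,-0.722264,0.01013
-10.5,-0.669379,0.00968841
-10,-0.616443,0.00928001
-9.5,-0.563461,0.00890493
-9,-0.510435,0.00856326
-8.5,-0.45737,0.00825513
-8,-0.404271,0.00798061
-7.5,-0.351141,0.0077398
-7,-0.297984,0.00753277
-6.5,-0.244804,0.00735957
-6,-0.191606,0.00722028
-5.5,-0.138393,0.00711492
-5,-0.0851693,0.00704352
-4.5,-0.0319394,0.00700612
-4,0.021293,0.00700272
-3.5,0.0745237,0.00703332
-3,0.127749,0.00709792
-2.5,0.180964,0.00719649
-2,0.234166,0.007329
-1.5,0.287349,0.00749542
-1,0.340511,0.00769569
-0.5,0.393647,0.00792975
0,0.446753,0.00819753
0.5,0.499825,0.00849895
1,0.552859,0.00883392
1.5,0.60585,0.00920233
2,0.658796,0.00960407
2.5,0.711691,0.010039
3,0.764533,0.0105071
3.5,0.817316,0.011008
4,0.870036,0.0115418
4.5,0.922691,0.0121082
5,0.975275,0.012707
5.5,1.02779,0.0133381
6,1.08022,0.0140012
6.5,1.13257,0.0146962
7,1.18483,0.0154229
7.5,1.237,0.0161811
8,1.28908,0.0169704
8.5,1.34056,0.0177984
9,1.38655,0.0187499
9.5,1.42534,0.0198827
10,1.4115,0.0204487
10.5,1.38654,0.0212084
11,1.35609,0.0223171
11.5,1.32065,0.0238391
12,1.28074,0.0258367
12.5,1.23693,0.0283685
13,1.18984,0.0314878
13.5,1.14008,0.0352413
14,1.0883,0.0396673
14.5,1.03516,0.0447942
15,0.981307,0.0506397
15.5,0.9274,0.0572094
16,0.874076,0.0644957
16.5,0.821955,0.0724776
17,0.771634,0.0811196
17.5,0.723676,0.090372
18,0.678608,0.100171
18.5,0.636918,0.110438
19,0.599043,0.121081
19.5,0.565375,0.131997
20,0.536249,0.143069
20.5,0.511946,0.154173
21,0.49269,0.165174
21.5,0.478646,0.175932
22,0.469919,0.186301
22.5,0.466554,0.196136
23,0.46854,0.205289
23.5,0.47538,0.213701
24,0.483044,0.222065
24.5,0.490561,0.230562
25,0.497929,0.239188
25.5,0.505145,0.247942
26,0.512207,0.25682
26.5,0.519113,0.26582
27,0.525861,0.27494
27.5,0.532449,0.284175
28,0.538874,0.293525
28.5,0.545136,0.302985
29,0.551231,0.312552
29.5,0.557159,0.322225
30,0.562917,0.332
35,0.6108,0.434687
40,0.640125,0.544129
45,0.65,0.657
50,0.640125,0.769871
55,0.6108,0.879313
60,0.562917,0.982
65,0.497929,1.07481
70,0.417812,1.15493
75,0.325,1.21992
80,0.222313,1.2678
85,0.112871,1.29713
90,7.9602e-17,1.307
95,-0.112871,1.29713
100,-0.222313,1.2678
105,-0.325,1.21992
110,-0.417812,1.15493
115,-0.497929,1.07481
120,-0.562917,0.982
125,-0.6108,0.879313
130,-0.640125,0.769871
135,-0.65,0.657
140,-0.640125,0.544129
145,-0.6108,0.434687
150,-0.562917,0.332
155,-0.497929,0.239188
160,-0.417812,0.159071
165,-0.325,0.0940835
170,-0.222313,0.0461998
175,-0.112871,0.016875
180,-1.59204e-16,0.007
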