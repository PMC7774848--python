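alpha_deg,cl,cd
-180,1.59204e-16,0.03
-175,0.112871,0.039875
-170,0.222313,0.0691998
-165,0.325,0.117083
-160,0.417812,0.182071
-155,0.497929,0.262188
-150,0.562917,0.355
-145,0.6108,0.457687
-140,0.640125,0.567129
-135,0.65,0.68
-130,0.640125,0.792871
-125,0.6108,0.902313
-120,0.562917,1.005
-115,0.497929,1.09781
-110,0.417812,1.17793
-105,0.325,1.24292
-100,0.222313,1.2908
-95,0.112871,1.32013
-90,-7.9602e-17,1.33
-85,-0.112871,1.32013
-80,-0.222313,1.2908
-75,-0.325,1.24292
-70,-0.417812,1.17793
-65,-0.497929,1.09781
-60,-0.562917,1.005
-55,-0.6108,0.902313
-50,-0.640125,0.792871
-45,-0.65,0.68
-40,-0.640125,0.567129
-35,-0.6108,0.457687
-30,-0.664265,0.32131
-29.5,-0.691762,0.30215
-29,-0.723232,0.282607
-28.5,-0.758361,0.262905
-28,-0.796794,0.243258
-27.5,-0.838135,0.22387
-27,-0.881948,0.204932
-26.5,-0.927766,0.186616
-26,-0.975091,0.169079
-25.5,-1.0234,0.152459
-25,-1.07216,0.136871
-24.5,-1.1208,0.122411
-24,-1.16876,0.109153
-23.5,-1.21548,0.0971485
-23,-1.26039,0.0864295
-22.5,-1.30292,0.0770058
-22,-1.34255,0.0688678
-21.5,-1.37875,0.0619875
-21,-1.41103,0.0563196
-20.5,-1.43892,0.0518037
-20,-1.462,0.0483655
-19.5,-1.47991,0.0459194
-19,-1.4923,0.0443703
-18.5,-1.49891,0.0436158
-18,-1.5,0.0435
-17.5,-1.5,0.0435
-17,-1.5,0.0435
-16.5,-1.48199,0.0431778
-16,-1.4312,0.04229
-15.5,-1.3803,0.0414313
-15,-1.32929,0.0406021
-14.5,-1.27818,0.0398025
-14,-1.22698,0.0390328
-13.5,-1.17568,0.0382933
-13,-1.12429,0.0375841
-12.5,-1.07281,0.0369056
-12,-1.02126,0.0362578
-11.5,-0.969623,0.035641
-11,-0.917915,0.0350554
-10.5,-0.866137,0.0345012
-10,-0.814293,0.0339784
-9.5,-0.762388,0.0334874
-9,-0.710424,0.0330282
-8.5,-0.658406,0.032601
-8,-0.606338,0.0322059
-7.5,-0.554224,0.031843
-7,-0.502067,0.0315124
-6.5,-0.449872,0.0312143
-6,-0.397643,0.0309487
-5.5,-0.345384,0.0307157
-5,-0.293099,0.0305154
-4.5,-0.240791,0.0303479
-4,-0.188465,0.0302131
-3.5,-0.136124,0.0301112
-3,-0.0837731,0.0300421
-2.5,-0.0314158,0.0300059
-2,0.0209439,0.0300026
-1.5,0.073302,0.0300322
-1,0.125655,0.0300947
-0.5,0.177997,0.0301901
0,0.230327,0.0303183
0.5,0.282639,0.0304793
1,0.334929,0.0306731
1.5,0.387194,0.0308995
2,0.439429,0.0311586
2.5,0.491631,0.0314502
3,0.543795,0.0317743
3.5,0.595918,0.0321307
4,0.647996,0.0325194
4.5,0.700024,0.0329402
5,0.751999,0.033393
5.5,0.803917,0.0338777
6,0.855774,0.0343941
6.5,0.907565,0.034942
7,0.959287,0.0355214
7.5,1.01094,0.036132
8,1.06251,0.0367735
8.5,1.114,0.037446
9,1.16541,0.038149
9.5,1.21672,0.0388825
10,1.26795,0.0396462
10.5,1.31908,0.0404398
11,1.37011,0.0412631
11.5,1.42103,0.0421159
12,1.47184,0.042998
12.5,1.5,0.0435
13,1.5,0.0435
13.5,1.5,0.0435
14,1.49948,0.0435274
14.5,1.49364,0.0438647
15,1.48154,0.0446559
15.5,1.46346,0.0459881
16,1.43974,0.0479463
16.5,1.4108,0.0506114
17,1.37708,0.0540585
17.5,1.33908,0.0583547
18,1.29733,0.0635575
18.5,1.2524,0.069713
19,1.20486,0.0768543
19.5,1.15533,0.085
20,1.10442,0.0941533
20.5,1.05274,0.1043
21,1.00091,0.11541
21.5,0.949524,0.127434
22,0.899182,0.140303
22.5,0.850444,0.153935
23,0.803847,0.168224
23.5,0.759899,0.183053
24,0.719066,0.198285
24.5,0.681775,0.21377
25,0.648408,0.229348
25.5,0.619298,0.244844
26,0.594727,0.260078
26.5,0.574924,0.274862
27,0.560065,0.289006
27.5,0.55027,0.302319
28,0.545604,0.314613
28.5,0.546078,0.325706
29,0.551231,0.335552
29.5,0.557159,0.345225
30,0.562917,0.355
35,0.6108,0.457687
40,0.640125,0.567129
45,0.65,0.68
50,0.640125,0.792871
55,0.6108,0.902313
60,0.562917,1.005
65,0.497929,1.09781
70,0.417812,1.17793
75,0.325,1.24292
80,0.222313,1.2908
85,0.112871,1.32013
90,7.9602e-17,1.33
95,-0.112871,1.32013
100,-0.222313,1.2908
105,-0.325,1.24292
110,-0.417812,1.17793
115,-0.497929,1.09781
120,-0.562917,1.005
125,-0.6108,0.902313
130,-0.640125,0.792871
135,-0.65,0.68
140,-0.640125,0.567129
145,-0.6108,0.457687
150,-0.562917,0.355
155,-0.497929,0.262188
160,-0.417812,0.182071
165,-0.325,0.117083
170,-0.222313,0.0691998
175,-0.112871,0.039875
180,-1.59204e-16,0.03
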