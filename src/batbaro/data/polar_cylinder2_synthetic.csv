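alpha_deg,cl,cd
-180,0,0.35
-175,0,0.35
-170,0,0.35
-165,0,0.35
-160,0,0.35
-155,0,0.35
-150,0,0.35
-145,0,0.35
-140,0,0.35
-135,0,0.35
-130,0,0.35
-125,0,0.35
-120,0,0.35
-115,0,0.35
-110,0,0.35
-105,0,0.35
-100,0,0.35
-95,0,0.35
-90,0,0.35
-85,0,0.35
-80,0,0.35
-75,0,0.35
-70,0,0.35
-65,0,0.35
-60,0,0.35
-55,0,0.35
-50,0,0.35
-45,0,0.35
-40,0,0.35
-35,0,0.35
-30,0,0.35
-29.5,0,0.35
-29,0,0.35
-28.5,0,0.35
-28,0,0.35
-27.5,0,0.35
-27,0,0.35
-26.5,0,0.35
-26,0,0.35
-25.5,0,0.35
-25,0,0.35
-24.5,0,0.35
-24,0,0.35
-23.5,0,0.35
-23,0,0.35
-22.5,0,0.35
-22,0,0.35
-21.5,0,0.35
-21,0,0.35
-20.5,0,0.35
-20,0,0.35
-19.5,0,0.35
-19,0,0.35
-18.5,0,0.35
-18,0,0.35
-17.5,0,0.35
-17,0,0.35
-16.5,0,0.35
-16,0,0.35
-15.5,0,0.35
-15,0,0.35
-14.5,0,0.35
-14,0,0.35
-13.5,0,0.35
-13,0,0.35
-12.5,0,0.35
-12,0,0.35
-11.5,0,0.35
-11,0,0.35
-10.5,0,0.35
-10,0,0.35
-9.5,0,0.35
-9,0,0.35
-8.5,0,0.35
-8,0,0.35
-7.5,0,0.35
-7,0,0.35
-6.5,0,0.35
-6,0,0.35
-5.5,0,0.35
-5,0,0.35
-4.5,0,0.35
-4,0,0.35
-3.5,0,0.35
-3,0,0.35
-2.5,0,0.35
-2,0,0.35
-1.5,0,0.35
-1,0,0.35
-0.5,0,0.35
0,0,0.35
0.5,0,0.35
1,0,0.35
1.5,0,0.35
2,0,0.35
2.5,0,0.35
3,0,0.35
3.5,0,0.35
4,0,0.35
4.5,0,0.35
5,0,0.35
5.5,0,0.35
6,0,0.35
6.5,0,0.35
7,0,0.35
7.5,0,0.35
8,0,0.35
8.5,0,0.35
9,0,0.35
9.5,0,0.35
10,0,0.35
10.5,0,0.35
11,0,0.35
11.5,0,0.35
12,0,0.35
12.5,0,0.35
13,0,0.35
13.5,0,0.35
14,0,0.35
14.5,0,0.35
15,0,0.35
15.5,0,0.35
16,0,0.35
16.5,0,0.35
17,0,0.35
17.5,0,0.35
18,0,0.35
18.5,0,0.35
19,0,0.35
19.5,0,0.35
20,0,0.35
20.5,0,0.35
21,0,0.35
21.5,0,0.35
22,0,0.35
22.5,0,0.35
23,0,0.35
23.5,0,0.35
24,0,0.35
24.5,0,0.35
25,0,0.35
25.5,0,0.35
26,0,0.35
26.5,0,0.35
27,0,0.35
27.5,0,0.35
28,0,0.35
28.5,0,0.35
29,0,0.35
29.5,0,0.35
30,0,0.35
35,0,0.35
40,0,0.35
45,0,0.35
50,0,0.35
55,0,0.35
60,0,0.35
65,0,0.35
70,0,0.35
75,0,0.35
80,0,0.35
85,0,0.35
90,0,0.35
95,0,0.35
100,0,0.35
105,0,0.35
110,0,0.35
115,0,0.35
120,0,0.35
125,0,0.35
130,0,0.35
135,0,0.35
140,0,0.35
145,0,0.35
150,0,0.35
155,0,0.35
160,0,0.35
165,0,0.35
170,0,0.35
175,0,0.35
180,0,0.35
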