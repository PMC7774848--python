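alpha_deg,cl,cd
-180,0,0.5
-175,0,0.5
-170,0,0.5
-165,0,0.5
-160,0,0.5
-155,0,0.5
-150,0,0.5
-145,0,0.5
-140,0,0.5
-135,0,0.5
-130,0,0.5
-125,0,0.5
-120,0,0.5
-115,0,0.5
-110,0,0.5
-105,0,0.5
-100,0,0.5
-95,0,0.5
-90,0,0.5
-85,0,0.5
-80,0,0.5
-75,0,0.5
-70,0,0.5
-65,0,0.5
-60,0,0.5
-55,0,0.5
-50,0,0.5
-45,0,0.5
-40,0,0.5
-35,0,0.5
-30,0,0.5
-29.5,0,0.5
-29,0,0.5
-28.5,0,0.5
-28,0,0.5
-27.5,0,0.5
-27,0,0.5
-26.5,0,0.5
-26,0,0.5
-25.5,0,0.5
-25,0,0.5
-24.5,0,0.5
-24,0,0.5
-23.5,0,0.5
-23,0,0.5
-22.5,0,0.5
-22,0,0.5
-21.5,0,0.5
-21,0,0.5
-20.5,0,0.5
-20,0,0.5
-19.5,0,0.5
-19,0,0.5
-18.5,0,0.5
-18,0,0.5
-17.5,0,0.5
-17,0,0.5
-16.5,0,0.5
-16,0,0.5
-15.5,0,0.5
-15,0,0.5
-14.5,0,0.5
-14,0,0.5
-13.5,0,0.5
-13,0,0.5
-12.5,0,0.5
-12,0,0.5
-11.5,0,0.5
-11,0,0.5
-10.5,0,0.5
-10,0,0.5
-9.5,0,0.5
-9,0,0.5
-8.5,0,0.5
-8,0,0.5
-7.5,0,0.5
-7,0,0.5
-6.5,0,0.5
-6,0,0.5
-5.5,0,0.5
-5,0,0.5
-4.5,0,0.5
-4,0,0.5
-3.5,0,0.5
-3,0,0.5
-2.5,0,0.5
-2,0,0.5
-1.5,0,0.5
-1,0,0.5
-0.5,0,0.5
0,0,0.5
0.5,0,0.5
1,0,0.5
1.5,0,0.5
2,0,0.5
2.5,0,0.5
3,0,0.5
3.5,0,0.5
4,0,0.5
4.5,0,0.5
5,0,0.5
5.5,0,0.5
6,0,0.5
6.5,0,0.5
7,0,0.5
7.5,0,0.5
8,0,0.5
8.5,0,0.5
9,0,0.5
9.5,0,0.5
10,0,0.5
10.5,0,0.5
11,0,0.5
11.5,0,0.5
12,0,0.5
12.5,0,0.5
13,0,0.5
13.5,0,0.5
14,0,0.5
14.5,0,0.5
15,0,0.5
15.5,0,0.5
16,0,0.5
16.5,0,0.5
17,0,0.5
17.5,0,0.5
18,0,0.5
18.5,0,0.5
19,0,0.5
19.5,0,0.5
20,0,0.5
20.5,0,0.5
21,0,0.5
21.5,0,0.5
22,0,0.5
22.5,0,0.5
23,0,0.5
23.5,0,0.5
24,0,0.5
24.5,0,0.5
25,0,0.5
25.5,0,0.5
26,0,0.5
26.5,0,0.5
27,0,0.5
27.5,0,0.5
28,0,0.5
28.5,0,0.5
29,0,0.5
29.5,0,0.5
30,0,0.5
35,0,0.5
40,0,0.5
45,0,0.5
50,0,0.5
55,0,0.5
60,0,0.5
65,0,0.5
70,0,0.5
75,0,0.5
80,0,0.5
85,0,0.5
90,0,0.5
95,0,0.5
100,0,0.5
105,0,0.5
110,0,0.5
115,0,0.5
120,0,0.5
125,0,0.5
130,0,0.5
135,0,0.5
140,0,0.5
145,0,0.5
150,0,0.5
155,0,0.5
160,0,0.5
165,0,0.5
170,0,0.5
175,0,0.5
180,0,0.5
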