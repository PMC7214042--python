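# power curve fit_mode=isotonic clamp_hi=14
# s	power
0	0.000000
1	0.000000
2	0.029412
3	0.066667
4	0.424242
5	0.424242
6	0.674419
7	0.674419
8	0.804124
9	0.804124
10	0.823529
11	0.823529
12	0.923077
13	0.923077
14	1.000000
15	1.000000
16	1.000000
17	1.000000
18	1.000000
19	1.000000
20	1.000000
21	1.000000
22	1.000000
23	1.000000
24	1.000000
25	1.000000
26	1.000000
27	1.000000
28	1.000000
29	1.000000
30	1.000000
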