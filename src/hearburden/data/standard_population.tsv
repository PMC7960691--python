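# hearburden-standard-population v1 (WHO World Standard-style weights, percent)
age_low	weight
0	8.86
5	8.69
10	8.60
15	8.47
20	8.22
25	7.93
30	7.61
35	7.15
40	6.59
45	6.04
50	5.37
55	4.55
60	3.72
65	2.96
70	2.21
75	1.52
80	0.91
85	0.44
90	0.15
95	0.04
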