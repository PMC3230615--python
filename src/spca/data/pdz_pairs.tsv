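position_i	position_j	r
4	5	0.6110
4	6	0.7217
5	4	0.6110
5	6	0.6163
6	4	0.7217
6	5	0.6163
6	7	0.6017
7	6	0.6017
26	27	0.7769
26	28	0.7058
27	26	0.7769
27	28	0.8039
27	29	0.6893
28	26	0.7058
28	27	0.8039
28	29	0.7083
28	30	0.6280
29	27	0.6893
29	28	0.7083
29	30	0.8635
29	31	0.6595
30	28	0.6280
30	29	0.8635
30	31	0.8007
30	32	0.6263
31	29	0.6595
31	30	0.8007
31	32	0.7713
31	33	0.6857
32	30	0.6263
32	31	0.7713
32	33	0.9105
32	34	0.7807
33	31	0.6857
33	32	0.9105
33	34	0.8587
34	32	0.7807
34	33	0.8587
50	51	0.8339
51	50	0.8339
65	66	0.6319
66	65	0.6319
75	76	0.6251
75	77	0.6207
76	75	0.6251
76	77	0.7074
76	79	0.6524
76	80	0.6704
77	75	0.6207
77	76	0.7074
77	78	0.6508
77	79	0.6543
77	80	0.6850
78	77	0.6508
78	79	0.7340
79	76	0.6524
79	77	0.6543
79	78	0.7340
79	80	0.6941
79	82	0.6015
79	83	0.7306
80	76	0.6704
80	77	0.6850
80	79	0.6941
80	81	0.6937
80	83	0.7206
81	80	0.6937
82	79	0.6015
83	79	0.7306
83	80	0.7206
90	92	0.6048
92	90	0.6048
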