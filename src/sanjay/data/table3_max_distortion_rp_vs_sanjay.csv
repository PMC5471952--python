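dataset_id,sanjay_max,rp_max,printed_ratio
1,1000,4069,4.07
2,1200,4179,3.48
3,1000,3982,3.98
4,1200,5289,4.4
5,1400,5045,3.6
6,1100,5092,4.62
7,1800,5364,2.98
8,1300,3566,2.74
9,1300,4357,3.35
10,1500,4262,2.84
11,1400,4945,3.53
12,1300,4370,3.36
13,1500,4747,3.16
14,1000,7029,7.02
15,1000,6161,6.16
16,1200,6732,5.61
17,1100,4298,3.9
18,1400,4922,3.51
19,1300,6719,5.16
20,1300,5583,4.29
21,1200,5311,4.42
22,1000,4447,4.44
23,1200,4731,3.94
24,1100,6251,5.68
25,1600,5919,3.69
26,1200,5385,4.48
27,1500,4886,3.25
28,1200,5884,4.9
29,1000,5398,5.3
30,1400,3900,2.78
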