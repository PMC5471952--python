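dataset_id,mds_max,sanjay_max,printed_ratio
1,3197.8,1000,3.197
2,2711.1,1200,2.259
3,1953.0,1000,1.953
4,2917.2,1200,2.431
5,3483.5,1400,2.488
6,2925.9,1100,2.659
7,4233.0,1800,2.351
8,2898.0,1300,2.229
9,1876.7,1300,1.443
10,4314.1,1500,2.876
11,3543.6,1400,2.531
12,2449.8,1300,1.884
13,3835.2,1500,2.556
14,4153.3,1000,4.153
15,2858.6,1000,2.858
16,3150.4,1200,2.625
17,2497.2,1100,2.27
18,2925.5,1400,2.089
19,3813.3,1300,2.933
20,3700.8,1300,2.846
21,3011.8,1200,2.509
22,3252.4,1000,3.252
23,3381.4,1200,2.817
24,2963.9,1100,2.694
25,3428.3,1600,2.142
26,2712.2,1200,2.26
27,3679.7,1500,2.453
28,3286.0,1200,2.738
29,2449.7,1000,2.449
30,4160.0,1400,2.971
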