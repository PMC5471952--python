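dataset_id,mds_avg,sanjay_avg
1,1042.4,540.8
2,1024.4,653.3
3,649.2,537.5
4,897.4,765.3
5,1089.6,806.3
6,1069.4,634.0
7,1374.4,1010.7
8,949.8,709.4
9,765.9,752.5
10,1011.7,892.9
11,1050.4,882.8
12,1050.3,760.0
13,1241.7,849.7
14,985.7,613.4
15,1249.6,612.4
16,1034.4,733.8
17,919.5,623.0
18,1056.8,822.4
19,1117.4,757.5
20,989.5,773.6
21,1057.5,684.8
22,1412.6,605.7
23,915.0,712.8
24,824.3,741.1
25,1178.1,1033.5
26,949.2,713.3
27,1114.2,833.6
28,935.4,611.7
29,1004.8,561.3
30,1178.4,874.1
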