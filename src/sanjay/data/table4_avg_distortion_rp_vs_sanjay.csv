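dataset_id,sanjay_avg,rp_avg,printed_ratio
1,540.8,1289.2,2.38
2,653.3,1226.5,1.87
3,537.5,1095.5,2.03
4,765.3,1637.1,2.13
5,806.3,1654.7,2.05
6,634.0,1555.5,2.45
7,1010.7,1608.8,1.59
8,709.4,1111.8,1.56
9,752.5,1439.5,1.91
10,892.9,1376.7,1.54
11,882.8,1578.5,1.78
12,760.0,1395.6,1.83
13,849.7,1363.1,1.6
14,613.4,2084.7,3.39
15,612.4,1916.6,3.12
16,733.8,1791.5,2.44
17,623.0,1361.3,2.18
18,822.4,1480.3,1.8
19,757.5,1912.7,2.52
20,773.6,1806.0,2.33
21,684.8,1535.2,2.24
22,605.7,1440.1,2.37
23,712.8,1355.4,1.9
24,741.1,1944.2,2.62
25,1033.5,1943.4,1.88
26,713.3,1762.9,2.47
27,833.6,1519.0,1.82
28,611.7,1648.0,2.69
29,561.3,1513.4,2.7
30,874.1,1047.5,1.19
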