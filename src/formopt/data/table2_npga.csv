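solution,x1,x2,x3_pct,y1,y2,surfactant_pct
1,0.79,2.32,75,0.12,0.82,15.8
2,0.67,1.07,75,0.15,0.75,13.4
3,0.75,0.28,74,0.17,0.64,15.8
4,0.63,1.85,75,0.13,0.81,12.6
5,0.77,1.53,74,0.14,0.70,16.2
6,0.67,2.08,74,0.12,0.71,14.1
7,0.64,1.05,74,0.14,0.61,13.4
8,0.78,0.65,75,0.16,0.69,15.6
9,0.63,1.06,74,0.14,0.62,13.2
10,0.60,0.62,75,0.16,0.69,12.0
11,0.62,2.06,75,0.13,0.82,12.4
12,0.68,3.62,74,0.11,0.81,14.3
13,0.77,2.88,75,0.12,0.85,15.4
14,0.74,2.65,73,0.11,0.63,16.3
15,0.68,1.21,75,0.14,0.72,13.6
16,0.60,0.44,75,0.17,0.70,12.0
17,0.68,1.49,75,0.13,0.75,13.6
18,0.70,1.06,74,0.14,0.69,14.7
19,0.72,0.65,74,0.15,0.62,15.1
20,0.68,0.89,75,0.15,0.77,13.6
21,0.68,1.93,73,0.12,0.63,15.0
22,0.79,4.00,74,0.11,0.80,16.6
23,0.61,0.72,75,0.15,0.68,12.2
24,0.74,0.53,75,0.16,0.73,14.8
25,0.66,1.23,75,0.14,0.74,13.2
26,0.79,1.58,74,0.13,0.60,16.6
27,0.60,1.75,75,0.13,0.74,12.0
28,0.77,3.26,74,0.11,0.76,16.2
29,0.62,3.55,74,0.12,0.81,13.0
30,0.77,2.48,75,0.12,0.80,15.4
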