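solution,x1,x2,x3_pct,y1,y2,surfactant_pct
1,0.78,0.43,75,0.17,0.74,15.6
2,0.75,0.35,75,0.17,0.74,15.0
3,0.63,0.57,75,0.16,0.73,12.6
4,0.68,1.84,74,0.12,0.65,14.3
5,0.64,0.98,75,0.15,0.76,12.8
6,0.69,1.37,74,0.14,0.71,14.5
7,0.80,0.96,73,0.15,0.49,17.6
8,0.79,0.39,75,0.17,0.73,15.8
9,0.79,0.29,75,0.18,0.72,15.8
10,0.66,0.38,75,0.17,0.73,13.2
11,0.63,1.81,72,0.11,0.50,14.5
12,0.75,1.13,75,0.15,0.78,15.0
13,0.63,1.04,75,0.15,0.77,12.6
14,0.70,0.75,75,0.16,0.76,14.0
15,0.77,0.30,74,0.17,0.64,16.2
16,0.75,1.41,74,0.14,0.70,15.8
17,0.62,2.21,75,0.13,0.85,12.4
18,0.60,3.94,75,0.13,1.01,12.0
19,0.68,1.42,75,0.14,0.80,13.6
20,0.69,0.46,74,0.16,0.66,14.5
21,0.68,1.28,75,0.14,0.80,13.7
22,0.61,0.40,74,0.16,0.63,12.8
23,0.68,0.70,74,0.15,0.67,14.3
24,0.74,1.34,75,0.14,0.79,14.8
25,0.61,0.43,75,0.17,0.71,12.2
26,0.67,3.79,75,0.12,0.99,13.4
27,0.65,0.32,75,0.17,0.72,13.0
28,0.62,2.06,74,0.13,0.74,13.0
29,0.66,0.49,75,0.16,0.74,13.2
30,0.72,0.79,74,0.15,0.67,15.1
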