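run,x1,x2,x3_pct,Y1_mean,Y1_sd,Y2_mean,Y2_sd,Y3_mean,Y3_sd,n_rep
1,0.8,0.25,70,0.1568,0.003,0.2629,0.026,17.83,3.668,6
2,0.8,1,65,0.1878,0.035,0.4089,0.015,13.64,0.340,6
3,0.8,1,75,0.1498,0.019,0.6672,0.340,16.31,1.849,6
4,0.8,4,70,0.0907,0.012,0.2670,0.035,23.21,0.594,6
5,0.7,0.25,65,0.1098,0.038,0.3216,0.045,20.13,0.109,6
6,0.7,0.25,75,0.1034,0.039,0.8754,0.072,22.98,0.390,6
7,0.7,4,65,0.0986,0.027,0.2787,0.028,19.86,0.247,6
8,0.7,4,75,0.1226,0.021,1.0292,0.376,22.70,0.376,6
9,0.6,0.25,70,0.1395,0.035,0.3090,0.182,42.38,0.182,6
10,0.6,1,75,0.1279,0.011,0.6596,0.025,41.36,0.157,6
11,0.6,1,65,0.0893,0.009,0.5231,0.071,36.35,0.183,6
12,0.6,4,70,0.0902,0.024,0.4388,0.139,41.39,0.149,6
13,0.7,1,70,0.1527,0.029,0.3586,0.094,20.78,0.183,6
14,0.7,1,70,0.1001,0.003,0.3167,0.032,20.81,0.132,6
15,0.7,1,70,0.1062,0.009,0.2928,0.026,21.31,0.128,6
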