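method,solution,x1,x2,x3_pct,y1,y2,max_fitness_gen,avg_fitness_gen
VEGA,29,0.65,0.83,75,0.15,0.75,9,9
MOGA,6,0.75,0.99,75,0.15,0.70,11,11
NPGA,20,0.68,0.89,75,0.15,0.77,7,7
NSGA,1,0.71,0.29,65,0.14,0.42,8,8
NSGA-II,2,0.75,0.35,75,0.17,0.74,3,3
NSGA-II,19,0.68,1.42,75,0.14,0.80,3,3
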