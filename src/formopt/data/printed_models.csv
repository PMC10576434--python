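term,Y1,Y2
b0,0.921,54.716
b1,2.312,-0.722
b2,0.041,-0.629
b3,-5.138,-57.078
b11,0.442,-3.039
b22,0.005,0.004
b33,5.847,110.563
b12,-0.044,-0.174
b13,-3.829,6.889
b23,-0.062,1.072
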