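run,temperature_c,time_min,acid_pct,solid_pct,r_rhamnose,r_glucose,r_xylose,r_glucuronic_acid,r_total,r_yield_pct
1,100,30,0,5,46.79,-7.64,-36.99,47.21,61.73,7.75
2,100,45,0.5,15,47.17,10.03,14.80,64.35,74.14,10.62
3,100,60,2,25,69.64,76.30,62.54,84.06,97.21,29.25
4,100,45,5,5,61.43,63.06,43.45,60.37,80.23,26.25
5,121,30,0.5,25,33.73,11.82,12.67,59.13,68.29,0.33
6,121,45,0,15,9.39,-60.00,-60.00,45.27,54.07,-9.45
7,121,60,5,5,61.66,62.83,38.35,58.98,79.69,25.71
8,121,30,2,15,71.44,74.31,56.58,69.14,90.54,27.02
9,134,30,2,25,76.75,78.21,60.46,71.79,94.63,26.67
10,134,45,5,25,74.33,77.62,49.55,69.03,92.68,24.72
11,134,60,0,15,9.99,-60.00,-60.00,44.98,53.77,-9.75
12,134,60,0.5,5,59.74,61.29,42.13,57.42,78.18,24.20
13,134,30,5,15,70.80,73.33,46.25,66.46,88.98,25.46
14,121,45,2,5,60.90,61.97,42.96,58.15,79.09,25.11
15,100,60,0.5,15,20.64,-4.44,-56.99,52.91,61.78,-1.75
16,134,45,0,25,9.38,-60.00,-60.00,41.88,50.71,-17.25
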