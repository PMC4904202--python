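run,temperature_c,time_min,acid_pct,solid_pct,rhamnose_mean,rhamnose_sd,glucose_mean,glucose_sd,xylose_mean,xylose_sd,glucuronic_acid_mean,glucuronic_acid_sd,total_mean,total_sd,yield_pct_mean,yield_pct_sd,density_mean,density_sd
1,100,30,0,5,218.7,5.2,0.2,0.1,0.4,0.1,238.6,163.6,1236.4,163.6,2.5,0.3,1000.5,0.6
2,100,45,0.5,15,228.7,10.3,3.2,0.1,5.5,0.1,1649.9,38.4,5095.5,75.6,3.4,0.1,1001.5,0.3
3,100,60,2,25,3036.1,51.3,6538.8,301.5,1339.9,13.6,16010.4,1111.5,72697.7,4020.8,29.1,1.6,1000.2,0.1
4,100,45,5,5,1179.1,13.3,1422.4,35.5,149.7,1.9,1058.9,149.1,10287.2,571.1,20.6,1.1,1004.2,0.3
5,121,30,0.5,25,49.2,6.7,4.3,1.6,4.8,0.0,942.4,218.6,2702.2,617.7,1.1,0.2,1001.6,0.2
6,121,45,0,15,3.0,0.1,0.001,0.0,0.0,0.0,329.7,277.1,898.1,748.3,0.6,0.5,1003.7,0.1
7,121,60,5,5,1215.8,93.7,1389.3,89.2,82.9,29.0,889.5,22.8,9659.3,446.2,19.3,0.9,1002.8,0.1
8,121,30,2,15,3739.7,185.2,5196.2,124.2,675.6,29.0,2866.8,71.6,33691.4,1107.2,22.5,0.7,1000.6,0.2
9,134,30,2,25,6879.6,43.2,8137.7,36.6,1054.2,4.8,3887.0,21.9,53888.2,287.5,21.6,0.1,1001.5,0.1
10,134,45,5,25,5218.8,284.5,7606.6,253.7,300.4,3.2,2829.6,77.7,43079.3,1671.7,17.2,0.7,1013.1,0.4
11,134,60,0,15,3.2,0.4,0.01,0.001,0.01,0.001,211.7,101.7,580.3,275.7,0.4,0.2,1008.2,1.1
12,134,60,0.5,5,976.1,87,1172.3,138.3,128.6,11.7,744.4,32.4,8157.7,727.7,16.3,1.5,1033.9,1.8
13,134,30,5,15,3510.8,445.1,4691.1,554.9,209.4,33.7,2120.7,222.1,28436.4,3390.7,19.0,2.3,1008.7,0.9
14,121,45,2,5,1109.7,12.3,1255.2,22.0,142.2,17.3,836.3,178.0,9027.0,553.6,18.1,1.1,1014.8,0.6
15,100,60,0.5,15,10.8,0.7,0.6,0.1,0.4,0.6,456.0,91.9,1263.2,248.4,0.8,0.2,1004.3,2.3
16,134,45,0,25,2.9,0.1,0.01,0.001,0.01,0.001,126.0,17.8,348.2,48.0,0.1,0.0,1008.0,0.5
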