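id,mental_demand,physical_demand,temporal_demand,performance,effort,frustration
01,6,1,1,2,1,3
02,6,1,3,4,2,3
03,4,1,18,0,7,9
04,8,1,4,2,3,5
05,10,2,6,4,4,2
06,12,3,12,2,14,3
07,14,2,4,2,4,2
08,5,1,2,1,4,3
10,7,1,3,4,4,3
11,15,1,1,5,11,1
12,2,1,5,20,1,1
13,10,1,10,15,8,2
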