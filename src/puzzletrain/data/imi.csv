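id,competence_effort,interest_enjoyment,value_usefulness,pressure_tension
01,13,45,13,21
02,13,41,9,19
03,8,32,2,21
04,14,41,5,19
05,11,29,3,21
06,10,40,11,19
07,13,42,12,20
08,13,40,5,14
10,13,38,9,18
11,14,44,13,21
12,13,43,4,18
13,13,37,4,14
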