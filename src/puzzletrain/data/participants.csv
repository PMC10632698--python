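id,group,age,gender,handedness,moca,tmt_a_s,tmt_b_s,smt_s
01,control,75,male,right,26,38,119,27
02,control,51,female,left,28,29,67,13
03,control,46,female,left,29,23,46,10
04,control,66,female,right,29,43,95,31
05,control,53,female,right,30,18,43,13
06,control,56,male,left,28,45,71,11
07,control,74,male,right,25,51,268,34
08,experimental,48,female,right,29,29,49,13
10,experimental,59,male,right,24,22,122,18
11,experimental,72,male,right,25,41,120,29
12,experimental,52,female,right,28,20,45,15
13,experimental,55,male,right,30,28,57,16
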