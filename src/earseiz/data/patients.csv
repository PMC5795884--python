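pid,n_seizures,sex,age,focus_side,focus_lobe,recording_h
1,1,F,19,right,occipital,12
2,9,F,24,left,temporal,91
3,8,M,32,right,temporal,52
4,1,M,64,left,temporal,3
5,2,M,61,right,temporal,27
6,2,F,33,right,parietal,23
7,5,M,45,left,temporal,34
8,6,F,32,left,temporal,72
9,2,F,49,left,temporal,43
10,1,M,28,right,temporal,21
11,3,F,25,right,temporal,10
12,7,M,20,left,temporal,43
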