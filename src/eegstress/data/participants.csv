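id,gender,age,pss_score,pss_label,expert_label
1,M,28,21,X,X
2,M,29,17,A,X
3,M,23,23,X,X
4,M,32,4,A,A
5,F,19,19,X,A
6,F,18,31,B,B
7,M,24,25,B,X
8,M,33,19,X,A
9,M,21,20,X,B
10,M,22,24,B,X
11,F,20,28,B,B
12,M,19,24,B,B
13,M,24,21,X,A
14,F,20,27,B,B
15,M,23,13,A,X
16,M,21,24,B,X
17,F,19,15,A,A
18,M,25,16,A,A
19,F,21,23,X,B
20,M,34,8,A,A
21,M,33,25,B,X
22,F,21,24,B,B
23,M,31,20,X,B
24,F,24,31,B,B
25,F,20,24,B,B
26,M,19,12,A,A
27,M,21,18,X,A
28,M,21,10,A,X
29,F,21,23,X,X
30,F,23,25,B,X
31,M,20,23,X,X
32,M,40,21,X,X
33,F,20,14,A,A
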