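cycle,age,rate
1,62.0,0.03281774005
2,63.0,0.03629713181
3,64.0,0.0401454145
4,65.0,0.04440169858
5,66.0,0.04910924101
6,67.0,0.05431588499
7,68.0,0.06007454607
8,69.0,0.06644375005
9,70.0,0.07348822769
10,71.0,0.08127957266
11,72.0,0.08989696906
12,73.0,0.09942799626
13,74.0,0.1099695189
14,75.0,0.1216286715
15,76.0,0.1345239469
16,77.0,0.148786401
17,78.0,0.1645609844
18,79.0,0.1654
19,80.0,0.1654
20,81.0,0.1654
21,82.0,0.1654
22,83.0,0.1654
23,84.0,0.1654
24,85.0,0.1654
25,86.0,0.1654
26,87.0,0.1654
27,88.0,0.1654
28,89.0,0.1654
29,90.0,0.1654
30,91.0,0.1654
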