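# Static channel -> Brodmann-area lookup for the 34-long-channel study montage.
# Labels are known only for the channels reported in the published post-hoc table
# and its discussion; the remaining channels are left blank (montage covers
# frontal, prefrontal and motor cortices: BAs 1, 4, 5, 6, 7, 8, 9, 10, 11, 40, 45, 46).
channel,brodmann_area
1,1-Orbitofrontal area
2,1-Orbitofrontal area
3,
4,
5,
6,
7,46-Dorsolateral prefrontal cortex
8,
9,
10,
11,
12,46-Dorsolateral prefrontal cortex
13,
14,9-Dorsolateral prefrontal cortex
15,9-Dorsolateral prefrontal cortex
16,
17,
18,6-Pre-Motor and Supplementary Motor Cortex
19,
20,
21,
22,
23,
24,
25,
26,
27,
28,4-Primary Motor Cortex
29,
30,
31,
32,
33,
34,
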