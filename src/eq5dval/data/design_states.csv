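index,label
1,11111
2,31122
3,22113
4,13212
5,12321
6,21231
7,22222
8,23311
9,11332
10,32131
11,31213
12,13123
13,12233
14,33221
15,21323
16,23132
17,32312
18,33333
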