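index,side_mm
1,18
2,22
3,27
4,32
5,38
6,46
7,52
8,55
9,89
10,100
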