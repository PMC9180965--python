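grade,images,eyes
0,331,149
1,142,62
2,94,37
3,15,5
4,6,3
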