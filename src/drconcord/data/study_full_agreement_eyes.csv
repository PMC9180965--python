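grade,images,eyes
0,789,361
1,40,20
2,6,3
3,6,1
4,0,0
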