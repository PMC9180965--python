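grade,patients
0,245
1,54
2,29
3,7
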