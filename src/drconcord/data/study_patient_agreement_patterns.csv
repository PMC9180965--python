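pattern,patients
P1_1_1_1,4
P2_1_1_AI_SINGLETON,80
P2_1_1_AI_IN_PAIR,7
P2_2,40
P3_1_AI_SINGLETON,99
P3_1_AI_WITH_MAJORITY,25
P4_0,112
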