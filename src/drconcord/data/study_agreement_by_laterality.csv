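scope,pattern,images,eyes
both,DISCORDANT_1_1_1,72,28
OS,DISCORDANT_1_1_1,41,15
OD,DISCORDANT_1_1_1,31,13
both,MAJORITY_2_1,588,256
OS,MAJORITY_2_1,294,129
OD,MAJORITY_2_1,294,127
both,UNANIMOUS_3_0,841,385
OS,UNANIMOUS_3_0,406,190
OD,UNANIMOUS_3_0,435,195
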