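patient_id,ai_grade
A,3
B,3
C,3
D,3
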