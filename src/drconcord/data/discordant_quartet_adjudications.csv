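patient_id,laterality,final_grade
A,OD,2
A,OS,2
B,OD,1
B,OS,1
C,OD,1
C,OS,1
D,OD,1
D,OS,1
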