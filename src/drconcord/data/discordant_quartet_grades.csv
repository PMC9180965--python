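patient_id,laterality,grader_id,grade,n_images
A,OD,grader1,0,2
A,OD,grader2,1,2
A,OD,grader3,2,2
A,OS,grader1,0,2
A,OS,grader2,1,2
A,OS,grader3,2,2
B,OD,grader1,0,2
B,OD,grader2,1,2
B,OD,grader3,2,2
B,OS,grader1,0,2
B,OS,grader2,1,2
B,OS,grader3,2,2
C,OD,grader1,2,2
C,OD,grader2,0,2
C,OD,grader3,1,2
C,OS,grader1,2,2
C,OS,grader2,0,2
C,OS,grader3,0,2
D,OD,grader1,0,2
D,OD,grader2,1,2
D,OD,grader3,2,2
D,OS,grader1,0,2
D,OS,grader2,1,2
D,OS,grader3,2,2
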