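subject,group,expert1_r1,expert1_r2,expert2_r1,expert2_r2,expert3_r1,expert3_r2,microct
Benign 1,benign,22,9,10,24,19,22,64
Benign 2,benign,5,8,8,6,8,7,25
Benign 3,benign,57,35,39,48,39,44,59
Benign 4,benign,18,10,10,10,16,14,15
Benign 5,benign,17,10,10,18,14,18,21
Malignant 1,malignant,12,9,9,14,12,9,13
Malignant 2,malignant,27,23,25,36,23,25,29
Malignant 3,malignant,34,28,29,44,44,46,214
Malignant 4,malignant,47,31,30,51,49,52,110
Malignant 5,malignant,27,9,9,26,25,23,27
Malignant 6,malignant,14,6,6,15,16,16,21
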