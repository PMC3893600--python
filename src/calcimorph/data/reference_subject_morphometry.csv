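subject,group,obj_v_mm3,obj_s_mm2,sv_per_mm,st_th_mm,smi,obj_n
Benign 1,benign,0.0150,0.28,142.86,0.27,2.88,64
Benign 2,benign,0.0237,0.37,59.53,0.30,3.69,24
Benign 3,benign,0.0203,0.37,51.01,0.29,3.13,59
Benign 4,benign,0.0050,0.14,79.07,0.20,3.07,15
Benign 5,benign,0.0156,0.34,55.93,0.22,2.96,21
Malignant 1,malignant,0.0269,0.49,84.85,0.26,2.94,13
Malignant 2,malignant,0.0075,0.20,46.46,0.20,3.10,29
Malignant 3,malignant,0.0024,0.08,99.66,0.18,3.05,214
Malignant 4,malignant,0.0041,0.13,77.26,0.18,3.10,110
Malignant 5,malignant,0.0028,0.10,76.80,0.15,3.08,27
Malignant 6,malignant,0.0031,0.10,101.12,0.17,3.03,21
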