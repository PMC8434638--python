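feature,mi_all,mi_teacher,mi_subject,mi_pleasure,mi_arousal
di_1D2D[0],0.0714,0.0908,0.0236,0.0148,0.0528
di_1D2D[1],0.0459,0.0000,0.0738,0.0228,0.0000
di_1Dur[0],0.0842,0.0000,0.0316,0.0694,0.0000
di_1Dur[1],0.0000,0.0923,0.0000,0.0592,0.0000
di_1KeyLat[0],0.0869,0.1108,0.0181,0.0120,0.0186
di_1KeyLat[1],0.0104,0.0044,0.1525,0.0000,0.0207
di_2Dur[0],0.0000,0.0000,0.0119,0.0003,0.0116
di_2Dur[1],0.0000,0.0500,0.0264,0.0000,0.0000
di_Dur[0],0.0455,0.0035,0.0634,0.0071,0.0150
di_Dur[1],0.0077,0.0000,0.0014,0.0000,0.0000
di_NumEvents[0],0.0000,0.0737,0.0000,0.0100,0.0000
di_NumEvents[1],0.0196,0.0543,0.0000,0.0466,0.0139
tri_1D2D[0],0.0747,0.0000,0.1038,0.0437,0.0000
tri_1D2D[1],0.0000,0.0000,0.0229,0.0000,0.0580
tri_1Dur[0],0.0539,0.0000,0.0769,0.0363,0.0000
tri_1Dur[1],0.0000,0.0731,0.0000,0.0323,0.0000
tri_1KeyLat[0],0.0103,0.0000,0.0014,0.0000,0.0000
tri_1KeyLat[1],0.0516,0.0547,0.0556,0.0000,0.0382
tri_2D3D[0],0.0356,0.0000,0.0425,0.0202,0.0609
tri_2D3D[1],0.0000,0.0045,0.0461,0.0000,0.0162
tri_2Dur[0],0.0000,0.0128,0.0000,0.0000,0.0000
tri_2Dur[1],0.0000,0.0429,0.0247,0.0000,0.0140
tri_2KeyLat[0],0.0270,0.0677,0.0246,0.0000,0.0285
tri_2KeyLat[1],0.0421,0.0000,0.1420,0.0000,0.0329
tri_3Dur[0],0.0000,0.0000,0.0000,0.0000,0.0000
tri_3Dur[1],0.0000,0.0408,0.0346,0.0094,0.0305
tri_Dur[0],0.0494,0.0000,0.0286,0.0661,0.0000
tri_Dur[1],0.0000,0.0000,0.0150,0.0456,0.0317
tri_NumEvents[0],0.0000,0.0000,0.0000,0.0351,0.0575
tri_NumEvents[1],0.0000,0.0562,0.0000,0.0136,0.0000
SPACE,0.0451,0.0773,0.0115,0.0137,0.0000
BCKSPACE,0.0000,0.0000,0.0548,0.0153,0.0004
DEL,0.0000,0.0000,0.0000,0.0516,0.0182
UP,0.0208,0.0000,0.0000,0.0018,0.0000
DOWN,0.0000,0.0000,0.0000,0.0578,0.0000
LEFT,0.0121,0.0206,0.0000,0.0315,0.0522
RIGHT,0.0000,0.0000,0.0000,0.0119,0.0506
SHIFT_L,0.0000,0.0000,0.0000,0.0535,0.0000
SHIFT_R,0.0195,0.0000,0.0000,0.0201,0.0521
L_di_1D2D[0],0.0000,0.0000,0.0000,0.0018,0.0000
L_di_1D2D[1],0.0126,0.1018,0.0705,0.0000,0.0000
L_di_Dur[0],0.0513,0.0315,0.0413,0.0000,0.0324
L_di_Dur[1],0.0000,0.0218,0.0000,0.0000,0.0226
L_first_shift_up,0.0103,0.0000,0.0000,0.0001,0.0000
R_di_1D2D[0],0.0000,0.0000,0.0000,0.0000,0.0610
R_di_1D2D[1],0.0000,0.0000,0.0000,0.0262,0.0001
R_di_Dur[0],0.0000,0.0000,0.0329,0.0139,0.0102
R_di_Dur[1],0.0000,0.0000,0.0000,0.0354,0.0000
R_first_shift_up,0.0000,0.0000,0.0000,0.0000,0.0000
CAPS,0.0264,0.0089,0.1154,0.0215,0.0000
SPEED,0.0504,0.1168,0.0000,0.0000,0.1211
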