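feature,p_all,p_teacher,p_subject
di_1D2D[0],0.0110,0.0862,0.0636
di_1D2D[1],0.0272,0.3060,0.0406
di_1Dur[0],0.9922,0.3446,0.3407
di_1Dur[1],0.6492,0.9741,0.5640
di_1KeyLat[0],0.0092,0.0365,0.1042
di_1KeyLat[1],0.0306,0.0964,0.1604
di_2Dur[0],0.2982,0.2786,0.6908
di_2Dur[1],0.8872,0.7062,0.5439
di_Dur[0],0.0456,0.2275,0.1146
di_Dur[1],0.2168,0.3095,0.4593
di_NumEvents[0],0.4972,0.2652,0.9736
di_NumEvents[1],0.9639,0.7703,0.8601
tri_1D2D[0],0.0404,0.2257,0.1012
tri_1D2D[1],0.0815,0.5219,0.0743
tri_1Dur[0],0.8501,0.3832,0.2019
tri_1Dur[1],0.4885,0.9490,0.3434
tri_1KeyLat[0],0.0425,0.1224,0.1821
tri_1KeyLat[1],0.0679,0.2338,0.1717
tri_2D3D[0],0.0245,0.0953,0.1279
tri_2D3D[1],0.0647,0.3188,0.1157
tri_2Dur[0],0.2479,0.1326,0.8699
tri_2Dur[1],0.3596,0.7236,0.3640
tri_2KeyLat[0],0.0085,0.0297,0.1092
tri_2KeyLat[1],0.0448,0.1235,0.1894
tri_3Dur[0],0.2469,0.2553,0.6115
tri_3Dur[1],0.8431,0.6929,0.4735
tri_Dur[0],0.0580,0.2302,0.1472
tri_Dur[1],0.6020,0.8435,0.6057
tri_NumEvents[0],0.5771,0.2485,0.8446
tri_NumEvents[1],0.9901,0.6742,0.7637
SPACE,0.0007,0.0052,0.0556
BCKSPACE,0.1130,0.1398,0.4749
DEL,0.1119,0.1755,0.3223
UP,0.6051,0.5610,0.9763
DOWN,0.2587,0.2395,0.9767
LEFT,0.8165,0.7099,0.7818
RIGHT,0.3073,0.7091,0.0382
SHIFT_L,0.9650,0.9601,0.8860
SHIFT_R,0.2980,0.5586,0.3935
L_di_1D2D[0],0.2593,0.7766,0.0879
L_di_1D2D[1],0.5596,0.6200,0.2197
L_di_Dur[0],0.1976,0.8832,0.0949
L_di_Dur[1],0.4886,0.9213,0.2769
L_first_shift_up,0.5827,0.5179,0.9156
R_di_1D2D[0],0.4292,0.7910,0.4325
R_di_1D2D[1],0.4109,0.8736,0.2713
R_di_Dur[0],0.7049,0.9507,0.6509
R_di_Dur[1],0.7665,0.9148,0.4554
R_first_shift_up,0.6406,0.5234,0.9910
CAPS,0.7135,0.3767,0.7256
SPEED,0.0068,0.0738,0.0439
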