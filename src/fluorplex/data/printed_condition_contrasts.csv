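analyte,contrast,fl_value,fl_chisq,fl_p,conc_value,conc_chisq,conc_p
April (42),Normal-COPD,-0.908,14.060,0.040,-0.656,4.678,1.000
April (42),Normal-Mono,1.383,69.060,0.000,1.484,54.024,0.000
Baff (37),Normal-Mono,-0.907,29.659,0.000,-0.319,2.492,1.000
CD163 (46),Normal-Mono,-0.775,21.684,0.001,-0.760,14.180,0.032
CD30 (53),Normal-Mono,-0.878,27.833,0.000,-0.861,18.190,0.004
IL-20 (30),Normal-Mono,-0.398,5.717,1.000,-0.779,14.901,0.022
IL-26 (22),Normal-Mono,-0.695,17.416,0.007,-1.031,26.082,0.000
IL-27 (13),Normal-Mono,-1.417,71.749,0.000,-1.796,58.714,0.000
MMP-1 (43),Normal-Mono,0.341,4.204,1.000,1.550,49.783,0.000
MMP-3 (45),Normal-Mono,1.043,39.227,0.000,,,
OCN (65),Normal-Mono,0.645,15.010,0.024,0.468,5.368,1.000
OPN (77),Normal-Mono,0.948,32.415,0.000,0.841,17.349,0.006
TNFR2 (67),Normal-Mono,-0.741,19.828,0.002,-0.606,9.008,0.473
April (42),Normal-Myeloma,1.831,70.681,0.000,2.055,53.370,0.000
IL-32 (35),Normal-Myeloma,-1.014,21.689,0.001,-1.428,16.454,0.010
MMP-1 (43),Normal-Myeloma,0.317,2.114,1.000,1.529,24.371,0.000
OCN (65),Normal-Myeloma,0.804,13.632,0.049,0.760,7.302,1.000
OPN (77),Normal-Myeloma,3.864,314.651,0.000,2.665,89.768,0.000
MMP-1 (43),Normal-Psoriasis,-1.286,29.022,0.000,-1.945,41.329,0.000
OPN (77),Normal-Psoriasis,1.669,48.862,0.000,1.067,12.881,0.063
April (42),Normal-RA,-0.737,13.852,0.044,-0.759,10.660,0.198
IFN-a2 (20),Normal-RA,-0.512,6.689,1.000,-1.025,19.217,0.002
IFN-b (44),Normal-RA,-0.750,14.350,0.034,-1.334,32.520,0.000
IFN-g (21),Normal-RA,-0.194,0.958,1.000,-1.256,13.492,0.046
IL-10 (56),Normal-RA,-1.357,47.009,0.000,-1.789,31.465,0.000
IL-11 (39),Normal-RA,-1.140,33.178,0.000,,,
IL-12p40 (28),Normal-RA,-0.608,9.423,0.450,-1.413,36.518,0.000
IL-12p70 (75),Normal-RA,-1.481,56.015,0.000,-2.429,107.861,0.000
IL-19 (29),Normal-RA,-1.152,33.862,0.000,-1.218,27.458,0.000
IL-2 (38),Normal-RA,-1.037,27.469,0.000,-2.470,105.001,0.000
IL-20 (30),Normal-RA,-1.563,62.396,0.000,-2.669,131.993,0.000
IL-22 (18),Normal-RA,-1.722,75.713,0.000,-3.814,148.767,0.000
IL-26 (22),Normal-RA,-0.536,7.335,1.000,-0.959,17.045,0.007
IL-27 (13),Normal-RA,-1.532,59.846,0.000,-2.300,65.341,0.000
IL-28 (66),Normal-RA,-0.543,7.523,1.000,-1.271,29.110,0.000
IL-29 (33),Normal-RA,-0.621,9.838,0.362,-2.215,53.627,0.000
IL-35 (34),Normal-RA,-1.006,25.855,0.000,-1.432,37.969,0.000
IL-8 (54),Normal-RA,-1.320,44.442,0.000,-1.076,21.460,0.001
TSLP (52),Normal-RA,-0.633,10.234,0.295,-1.225,27.796,0.000
April (42),Normal-Sepsis,-1.106,22.188,0.001,-0.747,6.568,1.000
Baff (37),Normal-Sepsis,-1.795,58.436,0.000,-1.115,14.626,0.025
Chitinase (72),Normal-Sepsis,-0.530,5.087,1.000,-1.111,13.591,0.043
IL-10 (56),Normal-Sepsis,-0.870,13.724,0.047,-0.903,6.364,1.000
IL-2 (38),Normal-Sepsis,-0.311,1.753,1.000,-1.314,19.372,0.002
IL-8 (54),Normal-Sepsis,-2.288,94.906,0.000,-1.581,29.423,0.000
MMP-1 (43),Normal-Sepsis,-2.248,91.631,0.000,-2.083,48.468,0.000
MMP-3 (45),Normal-Sepsis,-0.903,14.798,0.027,,,
Pentraxin (48),Normal-Sepsis,-0.952,16.419,0.012,-0.860,8.694,0.555
TNFR1 (73),Normal-Sepsis,-0.975,17.250,0.008,-1.355,21.622,0.001
TNFR2 (67),Normal-Sepsis,-1.282,29.817,0.000,-1.611,30.543,0.000
April (42),Normal-T2D,-0.751,17.352,0.007,-0.600,8.819,0.522
IFN-g (21),Normal-T2D,-0.329,3.340,1.000,-1.090,23.031,0.000
IL-12p40 (28),Normal-T2D,-0.184,1.044,1.000,-0.827,16.684,0.009
IL-2 (38),Normal-T2D,-0.094,0.272,1.000,-0.756,13.738,0.040
IL-28 (66),Normal-T2D,-0.222,1.510,1.000,-0.807,15.846,0.013
IL-29 (33),Normal-T2D,-0.256,2.022,1.000,-1.044,21.131,0.001
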