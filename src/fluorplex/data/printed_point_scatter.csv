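analyte,tissue,lod_fl,n_selected,n_above,n_below,cv_above,cv_below,ratio,f_pvalue
IFN-g (21),plasma,17.418,11,80,11,0.025,0.076,0.327,0.001
IFN-g (21),serum,17.418,28,52,28,0.059,0.081,0.724,0.064
IL-10 (56),plasma,34.966,29,29,62,0.161,0.129,1.248,0.472
IL-10 (56),serum,34.966,32,48,32,0.116,0.133,0.873,0.319
IL-11 (39),plasma,27.995,33,33,58,0.14,0.123,1.136,0.945
IL-11 (39),serum,27.995,37,37,43,1.239,0.146,8.469,0
IL-22 (18),plasma,27.463,12,79,12,0.016,0.092,0.173,0
IL-22 (18),serum,27.463,24,56,24,0.082,0.108,0.759,0.188
IL-27 (13),plasma,24.529,9,82,9,0.027,0.101,0.271,0.001
IL-27 (13),serum,24.529,23,56,23,0.157,0.155,1.013,0.461
IL-29 (33),serum,18.187,19,61,19,0.045,0.078,0.574,0.018
IL-32 (35),plasma,58.531,37,37,54,0.262,0.204,1.282,0.867
IL-32 (35),serum,58.531,39,41,39,0.322,0.284,1.131,0.902
IL-34 (15),plasma,60.664,16,16,75,0.229,0.177,1.296,0.868
IL-34 (15),serum,60.664,24,24,56,1.319,0.176,7.509,0
Light (51),plasma,136.28,29,62,29,0.059,0.116,0.505,0.001
Light (51),serum,136.28,8,72,8,0.049,0.106,0.465,0.056
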