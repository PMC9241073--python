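mutation,kd_nM,kd_sd_nM,kd_is_lower_bound,ddg_exp_printed_kcal,ddg_exp_printed_sd_kcal,ddg_comp_kcal,ddg_comp_sd_kcal,ddg_mmgbsa_kcal,ddg_mmgbsa_sd_kcal,ddg_alascan_kcal,ddg_alascan_sd_kcal,ddg_initial_kcal,ddg_initial_sd_kcal,ddg_initial_refined_kcal,ddg_initial_refined_sd_kcal
wild-type,20,4,false,0,0.12,-0.56,0.16,,,,,,,,
V8A,14,4,false,-0.21,0.17,-0.41,0.04,,,0.01,0.02,,,,
F28Y,15,5,false,-0.17,0.20,-0.20,0.05,,,,,1.4,0.2,,
Y32F,90,50,false,0.89,0.33,0.88,0.12,,,,,-1.5,0.1,-0.9,0.04
Y32K,680,90,false,2.09,0.08,1.55,0.22,,,,,,,,
V33N,28,5,false,0.20,0.11,-0.11,0.12,,,,,-1.3,0.1,,
T35S,520,82,false,1.93,0.09,1.67,0.05,,,,,-1.6,0.2,,
V36A,220,13,false,1.42,0.03,0.95,0.07,,,2.82,0.65,,,,
F37A,190,23,false,1.33,0.07,1.24,0.16,-0.27,0.12,4.11,1.03,,,,
D38A,2000,,true,2.73,,3.19,0.23,,,14.28,1.54,,,,
D38E,550,53,false,1.96,0.06,1.73,0.17,,,,,,,,
Y40C,1000,,true,2.32,,3.94,0.19,-0.95,0.15,,,,,,
V42A,40,8,false,0.41,0.12,0.39,0.08,,,2.26,0.74,,,,
M45T,30,4,false,0.24,0.08,-0.14,0.09,,,,,,,,
I46A,60,8,false,0.65,0.08,1.01,0.11,,,1.53,0.58,,,,
K135Q,15,5,false,-0.17,0.20,-0.12,0.20,,,,,,,,
L174A,250,9,false,0.54,0.11,1.28,0.12,,,0.69,0.43,,,,
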