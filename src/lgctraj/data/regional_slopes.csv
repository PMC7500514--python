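region,label,slope,slope_x_entry_age,loss20,random_slope_sd,random_slope_p,sex_p
caudal_middle_frontal,Caudal Middle Frontal,-0.556,-0.010,-12.726,0.125,0.563,0.074
frontal_pole,Frontal Pole,-0.663,-0.010,-14.831,0.458,0.076,0.479
lateral_orbitofrontal,Lateral Orbitofrontal,-0.385,-0.011,-9.546,0.108,0.887,0.125
medial_orbitofrontal,Medial Orbitofrontal,-0.363,-0.015,-9.726,0.162,0.937,0.371
para_central,Para-Central,-0.533,-0.002,-11.065,0.173,0.912,0.044
pars_opercularis,Pars Opercularis,-0.626,-0.005,-13.394,0.154,0.347,0.026
pars_orbitalis,Pars Orbitalis,-0.737,0.002,-14.437,0.001,1.000,0.367
pars_triangularis,Pars Triangularis,-0.682,0.005,-12.808,0.212,0.003,0.168
pre_central,Pre-Central,-0.631,-0.005,-13.446,0.214,0.359,0.051
rostral_middle_frontal,Rostral Middle Frontal,-0.533,-0.003,-11.261,0.043,0.633,0.024
superior_frontal,Superior Frontal,-0.548,-0.004,-11.655,0.178,0.342,0.010
inferior_parietal,Inferior Parietal,-0.677,-0.008,-14.904,0.190,0.487,0.113
post_central,Post-Central,-0.627,-0.000,-12.633,0.194,0.560,0.630
pre_cuneus,Pre-Cuneus,-0.641,-0.015,-15.256,0.186,0.548,0.015
superior_parietal,Superior Parietal,-0.592,-0.008,-13.117,0.072,0.203,0.010
supra_marginal,Supra Marginal,-0.577,-0.014,-13.769,0.209,0.143,0.015
banks_sup_temporal,Banks Sup Temporal,-0.505,-0.020,-13.354,0.223,0.110,0.019
entorhinal,Entorhinal,-0.379,-0.062,-17.423,0.782,3e-06,0.025
fusiform,Fusiform,-0.564,-0.029,-15.856,0.210,0.188,0.206
inferior_temporal,Inferior Temporal,-0.525,-0.022,-14.035,0.267,0.105,0.062
middle_temporal,Middle Temporal,-0.536,-0.017,-13.515,0.266,0.019,0.069
para_hippocampal,Para-Hippocampal,-0.395,-0.036,-13.702,0.341,0.004,0.033
superior_temporal,Superior Temporal,-0.660,-0.006,-14.250,0.224,0.172,0.021
temporal_pole,Temporal Pole,-0.545,-0.042,-17.623,0.598,1e-08,0.300
transverse_temporal,Transverse Temporal,-1.206,0.013,-22.089,0.211,0.374,0.004
cuneus,Cuneus,-0.624,0.011,-10.844,0.213,0.152,0.128
lateral_occipital,Lateral Occipital,-0.743,0.006,-13.958,0.257,0.068,0.433
lingual,Lingual,-0.618,0.006,-11.457,0.340,4e-04,0.101
pericalcarine,Peri-calcarine,-0.674,0.032,-8.330,0.490,0.016,0.616
caudal_anterior_cingulate,Caudal Anterior Cingulate,-0.282,-0.012,-7.575,0.005,0.992,0.010
isthmus_cingulate,Isthmus Cingulate,-0.437,-0.018,-11.589,0.328,0.002,0.026
posterior_cingulate,Posterior Cingulate,-0.544,-0.026,-15.013,0.200,0.457,0.005
rostral_anterior_cingulate,Rostral Anterior Cingulate,-0.289,0.001,-5.709,0.021,0.900,0.013
accumbens,Accumbens,-1.439,0.007,-27.643,0.429,0.063,0.956
amygdala,Amygdala,-0.383,-0.024,-11.455,0.481,6e-14,0.573
caudate,Caudate,-0.585,0.021,-8.305,0.463,3e-12,0.568
hippocampus,Hippocampus,-0.784,-0.040,-21.999,0.441,1e-13,0.286
insula,Insula,-0.499,-0.008,-11.262,0.307,0.003,0.016
pallidum,Pallidum,0.069,-0.013,-0.703,0.203,0.230,0.986
putamen,Putamen,-0.639,0.031,-7.850,0.326,1e-05,0.697
thalamus,Thalamus,-0.832,0.008,-15.409,0.240,3e-04,0.385
ventral_dc,Ventral DC,-0.516,0.006,-9.409,0.210,0.001,0.016
brain_stem,Brain Stem,-0.411,-0.000,-8.268,0.112,0.075,0.607
cerebellum_cortex,Cerebellum Cortex,-0.494,0.000,-9.818,0.147,0.193,0.827
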