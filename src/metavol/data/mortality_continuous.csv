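variable,mortality_pos_median,mortality_pos_q1,mortality_pos_q3,mortality_neg_median,mortality_neg_q1,mortality_neg_q3,p_value
age_years,63,58,67,60.5,47,69,0.453
ldh_u_per_l,372,212,565,297,206,432,0.112
albumin_g_per_dl,3.5,3.2,3.8,3.7,3.2,4.12,0.230
wbc_per_mm3,8800,6700,9800,9500,7775,12350,0.290
neutrophils_per_mm3,5800,4300,7600,6650,4775,8525,0.513
lymphocytes_per_mm3,1300,600,1700,1400,975,2300,0.186
platelets_per_mm3,276000,256000,365000,308000,259000,415750,0.465
suvmax_liver,19,13,22,24,19,27.25,0.003
suv_max,148,21,256,132,47.5,204,0.974
suv_peak,138,46,236,137.5,70,235.25,0.853
suv_mean,9.6,7.6,12.7,6.8,5.07,10.4,0.088
suvmean_liver,18,15,19,21,17,23.5,0.292
mtv_2_5,1089,560,2028,1498.5,413.75,4649.5,0.754
mtv_3_0,1378,644,6633,1432.5,242.25,4161.75,0.097
mtv_3_5,1194,725,5358,636,137.5,3628,0.121
suv_sd,3.4,1.8,4.9,2.4,1.5,4.0,0.407
pni,4.8,3.9,5.1,5.3,4,6.43,0.144
sii,1319,682,2650,1434.5,566.25,2519.5,0.686
nlr,5.15,2.63,8.63,4.38,1.98,7.98,0.401
hi1,0.3,0.24,0.39,0.31,0.25,0.38,0.744
hi2,185.5,27,476,93.5,5,2044,0.016
ki67_percent,75,50,80,75,65,80,0.475
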