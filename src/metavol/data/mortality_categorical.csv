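variable,category,mortality_pos_count,mortality_pos_pct,mortality_neg_count,mortality_neg_pct,p_value
age_group,> 60 years,13,61.9,25,51.0,0.402
age_group,<= 60 years,8,38.1,24,49.0,
gender,male,16,76.2,25,51.0,0.043
gender,female,5,23.8,24,49.0,
disease_stage,stage 1,4,19.0,10,20.4,0.971
disease_stage,stage 2,3,14.3,6,12.2,
disease_stage,stage 3,3,14.3,9,18.4,
disease_stage,stage 4,11,52.4,24,49.0,
stages_3_4,yes,14,66.7,33,67.3,0.956
comorbidity_ge1,yes,6,28.6,17,34.7,0.617
chemotherapy_regimen,R-EPOCH,3,14.3,9,18.4,0.678
chemotherapy_regimen,R-CHOP,18,85.7,40,81.6,
ecog_ps,score 1,9,42.9,24,49.0,0.842
ecog_ps,score 2,6,28.6,14,28.6,
ecog_ps,score 3,6,28.6,11,22.4,
ecog_ge2,yes,12,57.1,25,51.0,0.638
treatment_response,yes,19,90.5,49,100.0,0.028
complete_or_near_response,yes,10,47.6,24,49.0,0.917
relapse,yes,21,100.0,8,16.3,<0.001
elevated_ldh,yes,14,66.7,28,57.1,0.456
ipi_score,low / low-intermediate,15,71.4,30,61.2,0.414
ipi_score,high-intermediate / high,6,28.6,19,38.8,
bone_marrow_involvement,yes,2,11.8,3,8.6,0.714
bulky_disease,yes,5,23.8,10,20.4,0.751
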