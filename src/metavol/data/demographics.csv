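variable,category,count,percent
age,> 60 years,38,54.3
age,<= 60 years,32,45.7
sex,male,41,58.6
sex,female,29,41.4
stage,stage 1,14,20.0
stage,stage 2,9,12.9
stage,stage 3,12,17.1
stage,stage 4,35,50.0
advanced_stage,yes,47,67.1
advanced_stage,no,23,32.9
extranodal_gt1,yes,23,32.9
extranodal_gt1,no,47,67.1
regimen,R-EPOCH,12,17.1
regimen,R-CHOP,58,82.9
ecog,score 1,33,47.1
ecog,score 2,20,28.6
ecog,score 3,17,24.3
ecog_ge2,yes,37,52.9
ecog_ge2,no,33,47.1
treatment_response,response present,68,97.1
treatment_response,no response,2,2.9
response_type,complete or near complete,34,48.6
response_type,others,36,51.4
mortality,yes,21,30.0
mortality,no,49,70.0
relapse,yes,29,41.4
relapse,no,41,58.6
elevated_ldh,yes,42,60.0
elevated_ldh,no,28,40.0
ipi_group,low / low-intermediate,45,64.3
ipi_group,high-intermediate / high,25,35.7
bone_marrow,yes,5,7.1
bone_marrow,no,65,92.9
ki67,>= 70%,37,63.8
ki67,< 70%,21,36.2
bulky,yes,15,21.4
bulky,no,55,78.6
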