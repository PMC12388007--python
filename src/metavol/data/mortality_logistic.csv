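variable,coding,or_univariate,ci_low_univariate,ci_high_univariate,p_univariate,or_multivariate,ci_low_multivariate,ci_high_multivariate,p_multivariate
suvmax_liver,low (<= 22),8.000,2.080,30.763,0.002,7.116,1.750,28.932,0.006
hi2,low (<= 62.3),0.188,0.049,0.723,0.015,0.225,0.053,0.955,0.043
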