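variable,coding,or_univariate,ci_low_univariate,ci_high_univariate,p_univariate,or_multivariate,ci_low_multivariate,ci_high_multivariate,p_multivariate
ldh_u_per_l,low (<= 301),0.273,0.100,0.743,0.001,0.462,0.145,1.467,0.190
suvmax_liver,low (<= 21),3.293,1.218,8.908,0.019,2.577,0.841,7.899,0.098
hi2,low (<= 87.9),0.204,0.069,0.607,0.004,0.272,0.079,0.940,0.040
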