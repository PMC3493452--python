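covariate	value	prevalence	reference_mean
age	60	2%	50
age	70	8%	50
age	80	14%	50
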