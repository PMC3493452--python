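covariate	value	prevalence	reference_mean
bmi	18	2%	26.5
bmi	21.5	3%	26.5
bmi	24.5	5%	26.5
bmi	27.5	8%	26.5
bmi	30.5	13%	26.5
bmi	35	24%	26.5
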