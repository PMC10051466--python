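strain	tolerance	phenotype
BMA64-1A	30	HT
BY4742	26	HT
X2180-1A	24	HT
BY4741	22	LT
SEY6210	20	LT
S288C	20	LT
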