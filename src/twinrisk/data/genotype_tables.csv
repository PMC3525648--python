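cohort,group,freq_2copy,freq_1copy,freq_0copy
UCSF1,case,0.10,0.46,0.44
UCSF2,case,0.07,0.39,0.54
UCSF2,control,0.012,0.186,0.80
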