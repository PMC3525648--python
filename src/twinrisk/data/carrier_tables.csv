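cohort,group,carrier_freq
Canadian,case,0.55
Canadian,control,0.24
UCSF1,case,0.56
UCSF2,case,0.46
UCSF2,control,0.20
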