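zygosity,subgroup,concordant,discordant
MZ,carrier,9,31
MZ,non-carrier,11,42
MZ,F,22,66
MZ,M,2,43
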