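region,prevalence_low_per1e5,prevalence_high_per1e5,probandwise_mz_percent
Canada,68,248,25.3
Northern US,100,160,31.4
Southern US,22,112,17.4
Finland,52,93,46.2
Denmark,110,110,24
British Isles,74,193,40.0
France,32,65,11.1
Sardinia,144,152,22.2
Italy,38,90,14.5
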