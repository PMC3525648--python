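disease,prevalence_low_percent,prevalence_high_percent,probandwise_mz_percent
Rheumatoid arthritis,1,2,35
Ankylosing spondylitis,0.4,4,53
Systemic lupus erythematosus,0.025,0.025,39
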