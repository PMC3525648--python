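# Published table cells used by the reproduction harness.  Values are
# transcribed exactly as printed (i.e. rounded); `digits` is the printed
# number of decimals.  The harness recomputes each derivable cell at full
# precision and compares after half-up rounding at the printed precision.
T2:
  b:        {value: 0.134, digits: 3}
  t_female: {value: 0.183, digits: 3}
  s_male:   {value: 0.036, digits: 3}
T3:
  canadian_or_carrier: {value: 3.9, digits: 1}
  ucsf1_or_carrier:    {value: 4.0, digits: 1}
  ucsf2_or_1copy:      {value: 3.1, digits: 1}
  ucsf2_hwe_case_2copy: {value: 0.07, digits: 2}
  ucsf2_hwe_case_1copy: {value: 0.39, digits: 2}
  ucsf2_hwe_case_0copy: {value: 0.54, digits: 2}
T5:
  pairwise_carrier:        {value: 0.225, digits: 3}
  pairwise_noncarrier:     {value: 0.207, digits: 3}
  probandwise_carrier:     {value: 0.309, digits: 3}
  probandwise_noncarrier:  {value: 0.287, digits: 3}
  probandwise_pooled:      {value: 0.297, digits: 3}
  adjusted_carrier:        {value: 0.166, digits: 3}
  adjusted_noncarrier:     {value: 0.154, digits: 3}
  adjusted_pooled:         {value: 0.160, digits: 3}
  renormalized_carrier:    {value: 0.139, digits: 3}
  renormalized_noncarrier: {value: 0.129, digits: 3}
T6:
  pairwise_female:    {value: 0.25, digits: 2}
  pairwise_male:      {value: 0.044, digits: 3}
  pairwise_pooled:    {value: 0.18, digits: 2}
  probandwise_female: {value: 0.34, digits: 2}
  probandwise_male:   {value: 0.067, digits: 3}
  probandwise_pooled: {value: 0.25, digits: 2}
  adjusted_female:    {value: 0.183, digits: 3}
  adjusted_male:      {value: 0.036, digits: 3}
  adjusted_pooled:    {value: 0.134, digits: 3}
T8:
  # values in percent, one decimal
  Canada:        {lower: 0.4, upper: 3.6, digits: 1}
  Northern US:   {lower: 0.5, upper: 1.9, digits: 1}
  Southern US:   {lower: 0.2, upper: 2.4, digits: 1}
  Finland:       {lower: 0.2, upper: 0.7, digits: 1}
  Denmark:       {lower: 0.7, upper: 1.7, digits: 1}
  British Isles: {lower: 0.3, upper: 1.8, digits: 1}
  France:        {lower: 0.5, upper: 2.2, digits: 1}
  Sardinia:      {lower: 1.1, upper: 2.5, digits: 1}
  Italy:         {lower: 0.4, upper: 2.3, digits: 1}
T9:
  Rheumatoid arthritis:         {lower: 5.7, upper: 11.4, digits: 1}
  Ankylosing spondylitis:       {lower: 1.4, upper: 15, digits: 1, digits_upper: 0}
  Systemic lupus erythematosus: {lower: 0.13, upper: 0.13, digits: 2}

# Cells whose full-precision recomputation lands one unit of printed
# precision away from the published (rounded-intermediate) value.
known_discrepancies:
  - [T5, pairwise_noncarrier]
  - [T5, probandwise_pooled]
  - [T8, Canada lower]
  - [T8, Canada upper]
  - [T8, Northern US lower]
  - [T8, Denmark lower]
  - [T8, Italy lower]
  - [T9, Ankylosing spondylitis lower]
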