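# Multiple-sclerosis epidemiological observables (northern Europe / North
# America; Canadian twin registry).  All probabilities are decimals.
observables:
  prevalence: 0.0015
  mz_raw: 0.25          # proband-wise MZ concordance, pooled
  dz_raw: 0.054
  sib_raw: 0.029
  female_fraction_cases: 0.68
  carrier_fraction_cases: 0.55        # P(DRB1*1501 carrier | case), Canadian
  carrier_fraction_population: 0.24   # P(DRB1*1501 carrier), Canadian controls
  per_gender:
    F: {prevalence: 0.00204, mz_raw: 0.34, dz_raw: 0.051, sib_raw: 0.039}
    M: {prevalence: 0.00096, mz_raw: 0.067, dz_raw: 0.057, sib_raw: 0.019}

# Whole-study ascertainment calibration: total concordant/discordant MZ pairs
# and the registry's published overall proband-wise rate.
study:
  concordant: 24
  discordant: 109
  overall_probandwise: 0.253
  b_target: 0.134

environment:
  plateau_f: 0.28
  plateau_m: 0.06
  hazard_scale: 1.0
  r: 1.0
  n_events_min: 3

gender_partition:
  A: 0.68      # female fraction of cases
  A0: 0.50     # female fraction of the population
carrier_partition:
  A: 0.55
  A0: 0.24
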