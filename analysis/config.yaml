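# Study conditions shared by the analysis scripts.
seed: 1
markov:
  # England adult (18+) population, ONS mid-2015 estimate, millions
  adult_population: 42.9
  diabetes_total: 3.81   # PHE 2015 estimate, all diabetes, millions
  ih_total: 5.05         # PHE 2015 estimate, intermediate hyperglycaemia
  t2d_share: 0.9         # fraction of diabetes that is type 2
  baseline_year: 2015
  horizon: 2035
  ih_zero_variants: true
compare:
  years: [2015, 2020, 2025, 2030, 2035]
  include_published: true
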