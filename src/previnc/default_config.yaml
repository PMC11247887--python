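# Flat key-value configuration; every key here is overridable by the user
# config file passed to the CLI.
seed: 0
wave_years: [2000, 2006, 2012, 2018]
n_per_wave: 44000
age_range: [20, 79]
mrr_lo_range: [7.5, 8.5]   # MRR plausibility range at age 30
mrr_hi_range: [2.5, 3.0]   # MRR plausibility range at age 80
repetitions: 2000
derivative_method: analytic   # analytic | finite_difference
standard_population: survey   # 'survey' (pooled sample age structure) or a CSV path
output_dir: previnc_output
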