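# Default two-group cohort parameterisation: printed group means/SDs of the
# six salivary markers (relative-expression scale), group sizes, age model
# and covariate rates of the study cohort this package reanalyses.
n_control: 34
n_case: 33
distribution: lognormal
seed: 0
genes:
  MAOB:    {control_mean: 4.01, control_sd: 1.20, case_mean: 0.70, case_sd: 0.27}
  NAB2:    {control_mean: 2.11, control_sd: 0.42, case_mean: 0.49, case_sd: 0.05}
  COL3A1:  {control_mean: 1.55, control_sd: 0.20, case_mean: 0.62, case_sd: 0.12}
  NPIPB4:  {control_mean: 1.89, control_sd: 0.26, case_mean: 0.77, case_sd: 0.14}
  CYP27A1: {control_mean: 1.57, control_sd: 0.23, case_mean: 0.68, case_sd: 0.12}
  SIAE:    {control_mean: 1.18, control_sd: 0.24, case_mean: 0.73, case_sd: 0.11}
age:
  control: {mean: 53.2, sd: 17.4, min: 25.0, max: 83.0}
  case:    {mean: 61.2, sd: 18.1, min: 24.0, max: 97.0}
# Bernoulli rates per group (control, case); counts from the cohort table:
# male 15/34 vs 22/33, smoking 9/34 vs 9/33, alcohol 13/34 vs 11/33,
# mild periodontitis 3/34 vs 10/33.
covariates:
  male:          {control: 0.4412, case: 0.6667}
  smoking:       {control: 0.2647, case: 0.2727}
  alcohol:       {control: 0.3824, case: 0.3333}
  periodontitis: {control: 0.0882, case: 0.3030}
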