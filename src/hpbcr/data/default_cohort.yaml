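# Default synthetic-cohort calibration: per-class marginal summaries of a
# 579-patient breast-cancer registry cohort (recurrence prevalence 19.3%).
# Interval features give target mean/sd and hard bounds of the truncated-
# normal marginal per outcome class; nominal/ordinal features give per-class
# category probabilities. The involved/dissected node pair is drawn jointly
# (Gaussian copula) to a pooled Pearson correlation target; the nodal ratio
# and the molecular subtype are derived, never sampled.
prevalence: 0.193
node_correlation: 0.56
seed: 0
interval:
  age:
    recurrent:    {mean: 45.4, sd: 10.1, min: 27.0, max: 68.0}
    nonrecurrent: {mean: 47.2, sd: 9.9,  min: 24.0, max: 75.0}
  menarche:
    recurrent:    {mean: 13.3, sd: 1.3, min: 11.0, max: 17.0}
    nonrecurrent: {mean: 13.4, sd: 1.4, min: 10.0, max: 17.0}
  n_preg:
    recurrent:    {mean: 3.5, sd: 1.9, min: 0.0, max: 10.0}
    nonrecurrent: {mean: 3.7, sd: 2.1, min: 0.0, max: 10.0}
    integer: true
  ts:
    recurrent:    {mean: 4.0, sd: 1.7, min: 1.0, max: 8.5}
    nonrecurrent: {mean: 3.7, sd: 1.8, min: 0.5, max: 11.0}
  ki67:
    recurrent:    {mean: 21.1, sd: 12.6, min: 6.0, max: 74.0}
    nonrecurrent: {mean: 18.0, sd: 11.8, min: 1.0, max: 86.0}
  i_node:
    recurrent:    {mean: 6.6, sd: 7.3, min: 0.0, max: 39.0}
    nonrecurrent: {mean: 3.0, sd: 4.9, min: 0.0, max: 36.0}
    integer: true
  t_node:
    recurrent:    {mean: 12.8, sd: 6.1, min: 1.0, max: 39.0}
    nonrecurrent: {mean: 11.4, sd: 5.4, min: 1.0, max: 36.0}
    integer: true
  n_chemo:
    recurrent:    {mean: 7.7, sd: 0.9, min: 4.0, max: 10.0}
    nonrecurrent: {mean: 7.4, sd: 1.3, min: 1.0, max: 9.0}
    integer: true
nominal:
  fh:
    recurrent:    {pos: 0.18, neg: 0.82}
    nonrecurrent: {pos: 0.22, neg: 0.78}
  multifocal:
    recurrent:    {pos: 0.33, neg: 0.67}
    nonrecurrent: {pos: 0.27, neg: 0.73}
  er:
    recurrent:    {pos: 0.50, neg: 0.50}
    nonrecurrent: {pos: 0.57, neg: 0.43}
  pr:
    recurrent:    {pos: 0.50, neg: 0.50}
    nonrecurrent: {pos: 0.61, neg: 0.39}
  p53:
    recurrent:    {pos: 0.42, neg: 0.58}
    nonrecurrent: {pos: 0.34, neg: 0.66}
  surgery:
    recurrent:    {MRM: 0.51, BCS: 0.14, Mast: 0.35}
    nonrecurrent: {MRM: 0.56, BCS: 0.24, Mast: 0.20}
  her2:
    recurrent:    {pos: 0.58, neg: 0.42}
    nonrecurrent: {pos: 0.58, neg: 0.42}
  cathepsin:
    recurrent:    {pos: 0.93, neg: 0.07}
    nonrecurrent: {pos: 0.95, neg: 0.05}
  hrt:
    # published pair sums to 0.98; normalized on load (flagged)
    recurrent:    {pos: 0.55, neg: 0.43}
    nonrecurrent: {pos: 0.70, neg: 0.30}
  xrt:
    recurrent:    {pos: 0.99, neg: 0.01}
    nonrecurrent: {pos: 0.98, neg: 0.02}
ordinal:
  grade:
    recurrent:    {"1": 0.22, "2": 0.44, "3": 0.33, "4": 0.01}
    nonrecurrent: {"1": 0.10, "2": 0.59, "3": 0.29, "4": 0.02}
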