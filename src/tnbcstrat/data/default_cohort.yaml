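# Default cohort calibration, version 1.
#
# `crosstab` holds the published 317-case classifier-column x molecular-row
# cross-tabulation that the reference fixture reproduces and that the
# generator's priors and conditionals are derived from.  `hazard_ratios`
# carry the published LD-vs-LP contrasts per endpoint; the LAR and LI
# entries are plausible fill-ins (only the LD contrast is printed).
version: 1
crosstab:
  rows: [LAR, IM, BL1, M, UNC]
  columns: [LAR, LP, LI, LD]
  counts:
    LAR: [34, 1, 4, 6]
    IM: [10, 38, 7, 7]
    BL1: [1, 17, 23, 21]
    M: [13, 1, 10, 56]
    UNC: [13, 16, 15, 24]
# canonical readings used when realizing a drawn classified column
ar_high_values:          # (ar_percent, intensity) pairs, AR-high draws
  - [70, strong]
  - [80, strong]
  - [90, strong]
  - [100, strong]
ar_low_value: [0, negative]
til_values:              # TIL percentages available within each stratum
  LP_range: [60, 70, 80, 90, 100]
  LI_range: [20, 30, 40, 50]
  LD_range: [0, 10]
hazard_ratios:           # per endpoint, classified subtype vs LP
  os:  {LAR: 0.8, LP: 1.0, LI: 2.0, LD: 11.8}
  rfs: {LAR: 0.8, LP: 1.0, LI: 1.5, LD: 3.68}
  dfs: {LAR: 0.8, LP: 1.0, LI: 1.5, LD: 3.81}
baseline_hazard: 0.008   # events per month in the LP reference group
censor_rate: 0.01        # independent exponential censoring rate
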