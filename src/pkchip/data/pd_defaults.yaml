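# Calibrated defaults for the Emax-kill / damage-gate response model.
# Regenerate with scripts/calibrate_pd.py (coarse grid search over
# alpha, Emax_A, kout with Emax_S tuned to ~52% monotherapy GI at day 7).
params:
  kg: 0.3
  Emax_S: 1.402
  EC50_S: 2.0
  Emax_A: 0.5
  EC50_A: 50.0
  alpha: 2.0
  kin: 1.0
  kout: 0.75
  sigma: 0.0
  seed: 0
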