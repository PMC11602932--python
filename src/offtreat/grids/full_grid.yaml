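# Full factorial of the shipped simulation study: 2 discontinuation
# mechanisms x 4 discontinuation-rate pairs x 2 withdrawal rates x
# 3 withdrawal balances x 2 off-treatment trajectories = 96 scenarios.
grid:
  mechanism: [DAR, DNAR]
  disc_rates:
    - [0.10, 0.10]
    - [0.20, 0.20]
    - [0.50, 0.50]
    - [0.10, 0.20]
  withdrawal_rate: [0.5, 0.7]
  withdrawal_balance: [more_early, balanced, more_late]
  off_trajectory: [return_to_baseline, same_as_active]
n_per_arm: 375
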