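# Small synthetic demo cohort: 4 participants x 6 trials, all three
# display conditions, coupled imagery (lambda = 0.7).
output_dir: demo_out
seed: 7
synthetic:
  n_participants: 4
  n_trials: 6
  n_fixations: 40
n_boot: 500
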