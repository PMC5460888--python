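# Calibrated default simulation parameters.
#
# The LOH and background survivor rates are chosen (scripts/calibrate_sim.py)
# so that with targeting efficiency 1e-3 over 1.5e6 selected cells the mean
# non-LOH fraction among 18 picked colonies is ~0.40 for an MMR-abrogating
# variant and ~0.06 for a neutral one.
screen:
  targeting_efficiency: 1.0e-3
  n_cells_selected: 1500000
  loh_survivor_rate: 1.6588e-3
  background_survivor_rate: 1.0589e-4
  n_colonies_picked: 18

fluctuation:
  # n_start * 2**n_generations = 10027008 ~ 1e7
  n_start: 153
  n_generations: 16
  cells_per_plate: 100000
  n_plates: 100
  plating_efficiency: 1.0
  n_replicates: 4

mnng:
  cells_plated: 1500000
  n_replicates: 2
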