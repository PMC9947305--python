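# Two simulated colonies at the default study design:
# 247/249 exposed workers, 26/21 patrilines, 11 microsatellite loci.
seed: 1
simulate: {}
herit:
  monte_carlo_B: 5000
  min_workers: 5
tree:
  folds: 10
  cp: 0.01
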