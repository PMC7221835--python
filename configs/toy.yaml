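# Standard toy experiment: TM1-TM7 gate widened by 50%.
seed: 1
outdir: scratch/toy_run

layout:
  widen_gate: TM1-TM7
  widen_factor: 1.5

ligand:
  n_beads: 4
  head_charge: -1.0

dynamics:
  dt: 0.01          # ps
  temperature: 300.0
  friction: 1.0     # 1/ps

smd:
  k: 70.0           # pN/A
  v: 15.0           # m/s (reference all-atom protocol: 0.3)
  duration: 120.0   # ps
  repeats: 3
  n_pull_atoms: 1

sumd:
  arrival_radius: 4.0
  slice_length: 100
  epsilon: 0.1
  max_consecutive_rejects: 100
  max_total_steps: 400000
  start_site: outside_gate
  start_direction: TM1-TM7
  orientation: tail_first
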