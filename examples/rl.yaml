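# Stage 3: reward-aligned reinforcement learning with the surrogate scorer.
# sigma should track the log-probability scale of generated molecules
# (roughly 1-2 per sampled token): ~20 for the short fixture molecules,
# the 120 default for ~60-token drug-sized molecules.
stage: rl
seed: 0
out_dir: runs/rl
data:
  checkpoint: runs/pretrain/checkpoint.npz
  annotations: fixtures/annotations.jsonl
rl:
  steps: 60
  batch_size: 8
  sigma: 20.0
  lr: 0.0002
  temperature: 1.0
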