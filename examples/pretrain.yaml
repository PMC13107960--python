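# Stage 1: unconditional pretraining on an annotated corpus.
stage: pretrain
seed: 0
out_dir: runs/pretrain
data:
  annotations: fixtures/annotations.jsonl
model:
  d_model: 64
  n_layers: 2
  n_heads: 4
  K_bins: 16
train:
  epochs: 500
  lr: 0.003
  batch_size: 32
  loss_target: 0.005
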