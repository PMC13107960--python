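# Stage 2: pocket-conditional fine-tuning from a stage-1 checkpoint.
# Pockets come from the synthetic fixture families; swap in real
# protein-language-model embeddings via the pocket manifest for actual use.
stage: finetune
seed: 0
out_dir: runs/finetune
data:
  base_checkpoint: runs/pretrain/checkpoint.npz
  annotations: fixtures/annotations.jsonl
  n_pockets: 4
model:
  pocket_dim: 32
train:
  epochs: 150
  lr: 0.003
  batch_size: 8
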