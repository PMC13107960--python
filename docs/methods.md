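# Methods

This note documents the models and procedures implemented in `nummolgen`,
the choices made where the design was genuinely open, and what the synthetic
study conditions do and do not demonstrate.

## Problem setting

Structure-based generative design asks for molecules that bind a protein
pocket while staying drug-like and synthesizable. The number of functional
groups a molecule carries is a strong lever on that trade-off:
over-functionalization degrades physicochemical properties, while
under-functionalization costs binding interactions, and small structural
changes can collapse activity entirely (activity cliffs). `nummolgen`
implements a generator that takes *explicit per-group count constraints* —
a 27-dimensional integer vector — as conditioning, rather than only
qualitative "contains group X" hints.

## Functional-group triplets

A molecule is annotated as a set of triplets (type, number, positions), one
per entry of a fixed vocabulary. The default vocabulary enumerates the 27
named pharmacophoric feature definitions shipped with RDKit (donors,
acceptors, acidic/basic groups, Zn binders, aromatic rings of size 4–8,
hydrophobes and lumped hydrophobes), in file order, giving a deterministic
27-dimensional count space. Counts are numbers of *distinct atom sets*
matched by each SMARTS pattern: symmetric matches over the same atoms
collapse to one instance, overlapping instances of different types are all
retained, and atom indices are 0-based over the canonical-SMILES atom order.
Absent groups carry count 0 with an empty instance list, so all annotations
align entrywise. The test suite checks the counter against RDKit's
pharmacophore feature factory — an independent matching route — molecule by
molecule.

## Dual-sequence serialization

Each annotation becomes two aligned streams of equal length: discrete text
tokens and real numeric values. Counts ride in the numeric stream at `[NUM]`
positions; the text stream is zero-padded there and everywhere else the
numeric stream is zero. The template is:

1. **Constraint-summary prefix** — one `[NUM]` token per vocabulary group
   (27 positions), numeric values = the full count vector.
2. **Per-group blocks**, in vocabulary order:
   `[FG:name] [NUM] <p:i> … [SEP]` once per instance (`<p:k>` are
   atom-position tokens, `[SEP]` closes each instance), or
   `[FG:name] [NUM] [NONE]` for absent groups.
3. **SMILES body** — `[BOS]`, regex atom-level SMILES tokens, `[EOS]`.

The prefix exists for *conditioning order*: during constrained generation
the entire count vector is teacher-forced before any token is sampled.
Without it, instance positions of group *i* would have to be generated
before the counts of groups > *i* were visible, leaving the prompt
under-determined; in memorization experiments this cut exact reconstruction
from 100% to roughly 60–78%. The per-group `[NUM]` slots repeat each count
next to its positions and serve as the numeric head's regression targets.
Prefix counts are *excluded* from the numeric loss: they have no left
context, so their conditional variance is irreducible and would put a floor
under the loss that says nothing about model quality.

Token vocabulary layout is fixed: `[PAD]`(id 0), `[BOS]`, `[EOS]`, `[NUM]`,
`[SEP]`, `[NONE]`, one `[FG:name]` token per group, position tokens up to
the corpus' largest molecule, then SMILES tokens sorted lexicographically.
Position tokens are capped by a configurable maximum molecule size (default
128 atoms); larger molecules are rejected at annotation time.

## Network

A causal decoder over the dual sequence, written on the package's own
reverse-mode autodiff engine (`nummolgen.autodiff`, float32 by default,
float64 switchable for verification; gradients are pinned against finite
differences in the suite).

**Numerical embedding.** Each scalar `n` enters through three channels:
raw injection (`n` added to every coordinate of the token embedding), a
learned sign embedding with separate rows for −1/0/+1, and a soft magnitude
quantization: `|n|` passes through two small GELU MLPs (hidden width 32)
whose K=16-way softmaxes mix two learnable bin tables, the second scaled by
a learnable `lambda` (init 1.0). The fused stream is
`E_fusion = E_text + (n·1 + e_sign + e_mag)` — the raw text embedding is not
double-counted. Learned absolute position embeddings are added to `E_text`
and reach the fusion stream through the sum.

**Dual-stream differential attention.** Each block attends over both
streams with *shared* Q/K/V/output projections and isolates the numerical
increment as `H_diff = Attn(E_fusion) − Attn(E_text)`. The text stream
updates as a standard decoder block (`Norm(T + H_text)` then SwiGLU +
`Norm`); the fusion stream integrates only the differential signal
(`E' = Norm(F + H_diff)` then the same shared SwiGLU + `Norm`). `Norm` is
RMS normalization with a learned gain. Sharing the projections is what
makes the subtraction meaningful: with separate weights `H_diff` would
confound weight differences with the numerical increment. With the
numerical channel disabled there is a single stream, every `H_diff` is
exactly zero, and the network is bitwise a plain decoder — an identity the
acceptance suite asserts.

Cross-position information reaches the output heads only through the
accumulated `H_diff` terms; the text stream acts as a reference language
model. Both heads (next-token logits; a linear regression of the *next*
position's numeric value) read the fusion stream after a final RMS norm.
The numeric loss is masked to positions whose next token is `[NUM]` —
elsewhere the target is identically zero and would swamp the signal.

**Pocket conditioning.** Per-residue pocket embeddings (produced externally
by a frozen protein language model; the package consumes `.npy` matrices)
enter once, before the decoder stack, through a cross-attention layer:
queries from the RMS-normed fusion embeddings, keys/values from learned
projections of the pocket matrix, output projection **zero-initialized**.
Conditioning is therefore an exact no-op at initialization, which makes the
step-0 conditional loss equal the unconditional loss bitwise — the gating
contract under test.

**Generation.** The constraint header is teacher-forced: the prefix, every
`[FG:`/`[NUM]` token (numeric stream filled from the constraint vector),
and `[NONE]` for absent groups. Instance position tokens are sampled from
the model under a grammar mask (position tokens or `[SEP]` only; `[SEP]`
count pinned to the target count; at most 8 atoms per instance). After
`[BOS]`, SMILES tokens are sampled freely until `[EOS]` or the length cap.
Greedy, temperature and top-k modes are supported; temperature → 0
coincides with greedy. Invalid SMILES are legitimate outputs, filtered by
evaluation.

## Training

**Stage 1 — pretraining** minimizes mean next-token cross-entropy plus the
masked numeric MSE, `L = CE + MSE`, with Adam (lr 3e-3, full 32-molecule
batches at fixture scale) until a loss target or an epoch cap. The
memorization contract uses a purpose-built 32-molecule fixture whose count
vectors are pairwise distinct — a count-conditioned greedy decoder cannot
distinguish molecules sharing a vector, so collision-free vectors are a
precondition of the contract, not a convenience.

**Stage 2 — pocket-conditional fine-tuning** extends a pretrained model
with the zero-gated cross-attention (`add_pocket_conditioning`) and
continues under the same loss, batching by pocket. The fixture task pairs
each synthetic pocket with an exclusive molecule family (marker
substructures: carboxylic acid, nitrile, chloro, nitro); after fine-tuning,
matched (pocket, molecule) pairs score a lower loss than mismatched pairs.

**Stage 3 — RL.** Policy-gradient alignment with the augmented-likelihood
objective `E[(log pi_prior(S) + sigma R(S) − log pi_theta(S))^2]` against a
frozen copy of the starting policy. Log-probabilities are summed over the
SMILES body (the freely generated region). Invalid molecules receive reward
0 and stay in the loss; a long run of all-invalid batches aborts.

The reward is `R = 0.4·f(−dock, −3.0) + 0.3·f(QED, 0.2) + 0.3·f(SA, 0.5)`
with `f(x,b) = 1/(1+exp(−10(x−b)))`. The raw docking affinity (kcal/mol,
lower is better) is negated before the sigmoid so stronger binding raises
the reward. A consequence worth stating plainly: with the −3.0 threshold on
the negated scale, any realistic affinity (−2 kcal/mol or stronger) sits
several sigmoid widths above threshold, so the docking gate is effectively
saturated at 1 and reward variation is carried by the QED and SA terms. The
implementation keeps the printed constants; users docking against real
receptors can supply their own `dock_transform` / thresholds through
`RewardSpec`. SA enters on the normalized [0,1] scale, `(10 − raw)/9`,
higher = easier.

`sigma` trades prior retention against reward. Its useful magnitude tracks
the log-probability scale of a generated molecule (roughly 1–2 nats per
sampled token): the config default of 120 suits ~60-token molecules, while
the fixture corpus (~15-token SMILES bodies) uses `sigma = 20`. With a much
too large `sigma` the uniform residual offset dominates the per-sample
differences and early updates destabilize the policy before the reward
differential can steer it — observable as a dip-then-recover reward trace.

The RL improvement demonstration starts from a *partially* pretrained prior
(120 epochs, composite loss ≈ 0.15): such a prior still derails frequently
(mean sampled reward ≈ 0.08 because invalid molecules score 0), leaving
genuine headroom. A fully memorized prior is already at its reward ceiling,
and RL perturbation can only hurt it — the honest statement is that RL
sharpens an imperfect policy, not that it improves an optimal one. With
`sigma = 0` the objective is minimized at the prior and the policy provably
stays put (probe KL ≈ 0).

## Evaluation metrics

Validity = parseable fraction; uniqueness = distinct canonical SMILES over
valid; novelty = distinct valid not in a reference set. Lipinski compliance
is reported **both** ways the literature uses the word: fraction passing
all five rules, and mean rules satisfied (0–5), with the five-rule variant
standard in generative benchmarks (MW ≤ 500, HBD ≤ 5, HBA ≤ 10, logP ≤ 5,
rotatable bonds ≤ 10). QED from RDKit; SA from RDKit's contributed scorer,
normalized as above. Diversity = mean pairwise Tanimoto distance on Morgan
(radius 2, 2048-bit) fingerprints. Success rate applies the strict
inequalities Vina dock < −8.18, QED > 0.25, SA > 0.59; boundary values are
excluded.

Constraint compliance against target count vectors: MSE = mean over
molecules and the 27 groups of squared count error; EMR = fraction with
exact vector equality; FMR = fraction with every entry within ±3. The ±3
band applies to **all** groups, constrained or not. Invalid molecules count
as EMR/FMR failures and are excluded from the MSE with their count
reported, so EMR ≤ FMR holds on every batch by construction. Per-group
profiles report frequency ratio (fraction of molecules with ≥ 1 instance)
and average count, plus the mean squared difference of either statistic
between two collections.

## Synthetic study conditions

The fixture corpus enumerates small scaffold × substituent products (8
cores, 22 substituents, two-site cores take ordered pairs), canonicalized
and deduplicated — about 1,100 distinct molecules of ≤ 48 atoms whose
functional-group counts span 0 to ~6 per group. Pocket "embeddings" are
seeded unit-scale Gaussian matrices; they carry a learnable conditioning
signal but no biology. The surrogate docking score is a fixed smooth
function of heavy-atom count, ring count and logP, clipped to a realistic
kcal/mol range, so reward computations are bitwise reproducible.

What passing these tests shows: the codec is lossless, the architecture's
identities hold exactly, the training pipeline can drive its losses to
target and its policies toward reward on data whose structure it controls.
What it does not show: chemical generalization, real binding affinity, or
benchmark-scale constraint compliance — those require the full-size corpus
and a real docking engine, which are outside the package's test surface.

## Numerical choices and scale

Defaults: d_model 64, 2 layers, 4 heads, K = 16 magnitude bins, magnitude
MLP hidden 32, SwiGLU hidden 2·d_model, RMS-norm eps 1e-6, attention mask
additive −1e30, float32 tensors, Adam (β = 0.9/0.999, eps 1e-8). Problem
sizes used by the suite and the acceptance script — 32-molecule
memorization corpus, 1,000-molecule codec corpus, 100-molecule oracle
sample, 60 RL steps of batch 8 — were chosen so each stage completes in
minutes on one CPU while still exercising every contract at full strictness.
Ties in fixture selection break lexicographically; all randomness flows
from explicit seeds (the CLI derives per-purpose sub-seeds via SHA-256).

## Known limitations

- The block-to-block propagation of the two attention streams admits more
  than one self-consistent scheme; the implemented one (standard decoder
  updates on the text stream, differential-only residuals on the fusion
  stream, shared weights throughout) was chosen because it is the only
  variant under which the zero-channel reduction to a plain decoder holds
  exactly. Other propagation schemes would train differently.
- Count-only prompts cannot target molecules beyond the constraint's
  information content: distinct molecules with identical count vectors are
  indistinguishable to the generator by design.
- The numeric head regresses the next count; it is not used to *enforce*
  counts at generation time (counts are teacher-forced).
- Training is single-process CPU; no KV caching, so generation cost grows
  quadratically with sequence length. Adequate at fixture scale, not at
  benchmark scale.
- The dropout field exists in the config but regularization is unnecessary
  at memorization scale; it is not applied by the forward pass.
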