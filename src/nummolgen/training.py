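"""Three-stage training pipeline.

Stage 1 — unconditional pretraining on dual sequences with a composite loss:
mean next-token cross-entropy plus mean squared error of the numeric head,
``L = CE + MSE``.  The numeric MSE is restricted to positions whose *next*
token is ``[NUM]`` (elsewhere the target is identically zero and would swamp
the signal).

Stage 2 — pocket-conditional fine-tuning: same loss, with per-residue pocket
embeddings entering through the zero-initialized cross-attention, so the
conditional loss at step 0 equals the unconditional loss exactly.

Stage 3 — policy-gradient RL with an augmented-likelihood objective

    L(theta) = E[ (log pi_prior(S) + sigma * R(S) - log pi_theta(S))^2 ]

against a frozen prior, where the reward blends a docking score, QED and
normalized synthetic accessibility through sigmoid gates:

    R = 0.4 f(-dock, -3.0) + 0.3 f(QED, 0.2) + 0.3 f(SA, 0.5),
    f(x, b) = 1 / (1 + exp(-10 (x - b))).

The raw docking affinity (kcal/mol, lower is better) is negated before the
sigmoid so that stronger binding raises the reward; invalid generated SMILES
receive reward 0 and stay in the loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from .autodiff import Adam, Tensor, log_softmax
from .exceptions import (
    ConfigurationError,
    ContractViolation,
    DegenerateBatchError,
    DivergenceError,
    NumericDomainError,
    ScoringError,
)
from .model import ModelConfig, DualStreamGenerator, ProteinContext
from .sequence import NUM, DualSequence, TokenVocabulary, pad_batch


@dataclass
class CompositeLossTerms:
    ce_token: float
    mse_numeric: float

    @property
    def total(self) -> float:
        return self.ce_token + self.mse_numeric


def composite_loss(
    token_logits: Tensor,
    numeric_preds: Tensor,
    text: np.ndarray,
    numeric: np.ndarray,
    mask: np.ndarray,
    num_token_id: int,
    numeric_target_start: int = 0,
) -> tuple[Tensor, CompositeLossTerms]:
    """Next-token CE plus numeric-slot MSE for a padded batch.

    ``text``/``numeric``/``mask`` are the ``(B, L)`` inputs the logits were
    computed from; position ``t`` predicts position ``t+1``.  The MSE is
    restricted to positions whose next token is ``[NUM]`` and whose index is
    at least ``numeric_target_start`` — the constraint-summary prefix is
    conditioning, not a regression target (its values have no left context
    to be predicted from).
    """
    text = np.asarray(text)
    mask = np.asarray(mask, dtype=bool)
    B, L = text.shape
    valid_next = mask[:, 1:]  # (B, L-1): positions with a real next token
    if not valid_next.any():
        raise DegenerateBatchError("no unmasked next-token positions in batch")
    rows_b, rows_t = np.nonzero(valid_next)
    targets = text[rows_b, rows_t + 1]
    logp = log_softmax(token_logits, axis=-1)
    ce = -(logp[rows_b, rows_t, targets].mean())

    num_next = valid_next & (text[:, 1:] == num_token_id)
    num_next[:, : max(numeric_target_start - 1, 0)] = False
    if num_next.any():
        nb, nt = np.nonzero(num_next)
        target_vals = numeric[nb, nt + 1]
        diff = numeric_preds[nb, nt] - Tensor(target_vals)
        mse = (diff * diff).mean()
    else:
        mse = Tensor(0.0)
    total = ce + mse
    terms = CompositeLossTerms(float(ce.data), float(mse.data))
    if not math.isfinite(terms.total):
        raise DivergenceError(f"non-finite loss: {terms}")
    return total, terms


@dataclass
class TrainConfig:
    """Optimizer and schedule defaults for the pretraining/fine-tuning stages."""

    epochs: int = 400
    lr: float = 3e-3
    batch_size: int = 32
    loss_target: float = 0.05  # early stop once the epoch loss drops below
    log_every: int = 20


def _prefix_length(seq: DualSequence, num_id: int) -> int:
    """Length of the leading [NUM] run (the constraint-summary prefix)."""
    n = 0
    for tid in seq.text_ids:
        if int(tid) != num_id:
            break
        n += 1
    return n


def pretrain(
    corpus: Sequence[DualSequence],
    model_config: ModelConfig,
    tok_vocab: TokenVocabulary,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    log: Callable[[dict], None] | None = None,
) -> tuple[DualStreamGenerator, list[CompositeLossTerms]]:
    """Train a fresh model on encoded dual sequences (unconditional stage)."""
    if not corpus:
        raise ConfigurationError("pretraining corpus is empty")
    tc = train_config or TrainConfig()
    model = DualStreamGenerator(model_config, seed=seed)
    history = train_model(model, corpus, tok_vocab, tc, seed=seed, log=log)
    return model, history


def train_model(
    model: DualStreamGenerator,
    corpus: Sequence[DualSequence],
    tok_vocab: TokenVocabulary,
    tc: TrainConfig,
    seed: int = 0,
    contexts: Sequence[ProteinContext] | None = None,
    log: Callable[[dict], None] | None = None,
) -> list[CompositeLossTerms]:
    """Shared optimization loop for stages 1 and 2.

    With ``contexts`` (one per sequence) the batch iterator groups samples by
    pocket so each forward pass conditions on a single pocket matrix.
    """
    rng = np.random.default_rng(seed)
    max_len = max(len(s) for s in corpus)
    num_id = tok_vocab.id(NUM)
    prefix_len = _prefix_length(corpus[0], num_id)
    opt = Adam(model.parameters(), lr=tc.lr)
    history: list[CompositeLossTerms] = []

    if contexts is not None and len(contexts) != len(corpus):
        raise ContractViolation("one ProteinContext required per sequence")

    groups: list[np.ndarray]
    if contexts is None:
        groups = [np.arange(len(corpus))]
    else:
        by_pocket: dict[str, list[int]] = {}
        for i, c in enumerate(contexts):
            by_pocket.setdefault(c.pocket_id, []).append(i)
        groups = [np.array(v) for _, v in sorted(by_pocket.items())]

    for epoch in range(tc.epochs):
        epoch_ce, epoch_mse, n_batches = 0.0, 0.0, 0
        for group in groups:
            perm = group[rng.permutation(len(group))]
            for start in range(0, len(perm), tc.batch_size):
                idx = perm[start : start + tc.batch_size]
                seqs = [corpus[i] for i in idx]
                text, numeric, mask = pad_batch(seqs, max_len)
                ctx = contexts[idx[0]] if contexts is not None else None
                logits, preds = model.forward(text, numeric, ctx=ctx)
                loss, terms = composite_loss(
                    logits, preds, text, numeric, mask, num_id,
                    numeric_target_start=prefix_len,
                )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_ce += terms.ce_token
                epoch_mse += terms.mse_numeric
                n_batches += 1
        terms = CompositeLossTerms(epoch_ce / n_batches, epoch_mse / n_batches)
        history.append(terms)
        if log is not None and (epoch % tc.log_every == 0 or terms.total < tc.loss_target):
            log({"epoch": epoch, "ce": terms.ce_token, "mse": terms.mse_numeric,
                 "total": terms.total})
        if terms.total < tc.loss_target:
            break
    return history


def finetune_conditional(
    pairs: Sequence[tuple[ProteinContext, DualSequence]],
    model: DualStreamGenerator,
    tok_vocab: TokenVocabulary,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    log: Callable[[dict], None] | None = None,
) -> tuple[DualStreamGenerator, list[CompositeLossTerms]]:
    """Stage 2: fine-tune a pretrained model on (pocket, molecule) pairs."""
    if not pairs:
        raise ConfigurationError("no conditional training pairs supplied")
    if model.cross is None:
        raise ConfigurationError(
            "model has pocket_dim=0; rebuild with pocket conditioning enabled"
        )
    d_p = model.config.pocket_dim
    for ctx, _ in pairs:
        if ctx.embeddings.shape[1] != d_p:
            raise ConfigurationError(
                f"pocket embedding dim {ctx.embeddings.shape[1]} != pocket_dim {d_p}"
            )
    tc = train_config or TrainConfig()
    contexts = [c for c, _ in pairs]
    corpus = [s for _, s in pairs]
    history = train_model(model, corpus, tok_vocab, tc, seed=seed,
                          contexts=contexts, log=log)
    return model, history


# ---------------------------------------------------------------------------
# Reward


def sigmoid_normalize(x: float, b: float, k: float) -> float:
    """Numerically stable ``1 / (1 + exp(-k (x - b)))``; increasing in x."""
    if not (math.isfinite(x) and math.isfinite(b) and math.isfinite(k)):
        raise NumericDomainError("sigmoid_normalize requires finite inputs")
    z = k * (x - b)
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def _negate(x: float) -> float:
    return -x


@dataclass
class RewardSpec:
    """Weights, thresholds and sigmoid scale of the multi-objective reward.

    ``dock_transform`` maps the raw docking affinity to the score fed to the
    sigmoid; the default negates it (kcal/mol, lower is better), so the
    threshold ``b_dock = -3.0`` lives on the negated scale.
    """

    w_dock: float = 0.4
    w_qed: float = 0.3
    w_sa: float = 0.3
    b_dock: float = -3.0
    b_qed: float = 0.2
    b_sa: float = 0.5
    k: float = 10.0
    dock_transform: Callable[[float], float] = _negate

    def __post_init__(self):
        w = (self.w_dock, self.w_qed, self.w_sa)
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ConfigurationError("reward weights must be non-negative and sum to 1")
        if self.k <= 0:
            raise ConfigurationError("sigmoid scale k must be positive")


def reward(dock_score: float | None, qed: float | None, sa: float | None,
           spec: RewardSpec | None = None) -> float:
    """Weighted sigmoid blend of docking, QED and normalized SA; in (0, 1)."""
    spec = spec or RewardSpec()
    if dock_score is None or qed is None or sa is None:
        raise ScoringError("all three reward components must be provided")
    return (
        spec.w_dock * sigmoid_normalize(spec.dock_transform(dock_score), spec.b_dock, spec.k)
        + spec.w_qed * sigmoid_normalize(qed, spec.b_qed, spec.k)
        + spec.w_sa * sigmoid_normalize(sa, spec.b_sa, spec.k)
    )


class MoleculeScorer(Protocol):
    """Pluggable provider of (docking affinity, QED, normalized SA)."""

    def score(self, smiles: str) -> tuple[float, float, float] | None:
        """Scores for a SMILES, or ``None`` if the molecule is invalid."""
        ...


# ---------------------------------------------------------------------------
# Reinforcement learning


def rl_loss(logp_prior: float, logp_theta: Tensor, R: float, sigma: float) -> Tensor:
    """Per-sample augmented-likelihood loss ``(logp_prior + sigma R - logp_theta)^2``."""
    if not (math.isfinite(logp_prior) and math.isfinite(float(logp_theta.data))):
        raise DivergenceError("non-finite log-probability in RL loss")
    diff = Tensor(logp_prior + sigma * R) - logp_theta
    return diff * diff


@dataclass
class RLConfig:
    steps: int = 40
    batch_size: int = 8
    sigma: float = 120.0
    lr: float = 1e-4
    temperature: float = 1.0
    max_consecutive_invalid: int = 20


@dataclass
class RLState:
    """Bookkeeping for an RL run (prior stays frozen throughout)."""

    policy: DualStreamGenerator
    prior: DualStreamGenerator
    sigma: float
    step: int = 0
    reward_trace: list[float] = field(default_factory=list)


def rl_finetune(
    model: DualStreamGenerator,
    tok_vocab: TokenVocabulary,
    fg_names: Sequence[str],
    scorer: MoleculeScorer,
    constraint_vectors: Sequence[np.ndarray],
    rl_config: RLConfig | None = None,
    reward_spec: RewardSpec | None = None,
    seed: int = 0,
    ctx: ProteinContext | None = None,
    log: Callable[[dict], None] | None = None,
) -> RLState:
    """Stage 3: align the policy with the multi-objective reward.

    Each step samples a batch of molecules under constraint headers drawn
    from ``constraint_vectors``, scores them, and minimizes the mean
    augmented-likelihood loss.  The prior is a deep frozen copy of the
    starting policy.  Invalid SMILES get reward 0 and stay in the loss;
    a long run of all-invalid batches aborts.
    """
    rc = rl_config or RLConfig()
    spec = reward_spec or RewardSpec()
    rng = np.random.default_rng(seed)
    prior = model.copy()
    state = RLState(policy=model, prior=prior, sigma=rc.sigma)
    opt = Adam(model.parameters(), lr=rc.lr)
    consecutive_invalid = 0

    for step in range(rc.steps):
        losses: list[Tensor] = []
        rewards: list[float] = []
        for b in range(rc.batch_size):
            cvec = constraint_vectors[int(rng.integers(len(constraint_vectors)))]
            sample_seed = int(rng.integers(2**31 - 1))
            seq, prompt_len, smiles = sample_sequence(
                model, cvec, tok_vocab, fg_names, ctx=ctx,
                temperature=rc.temperature, seed=sample_seed,
            )
            scores = scorer.score(smiles)
            R = 0.0 if scores is None else reward(*scores, spec=spec)
            rewards.append(R)
            logp_theta = model.sequence_log_prob(seq, prompt_len, ctx=ctx)
            logp_prior = float(prior.sequence_log_prob(seq, prompt_len, ctx=ctx).data)
            losses.append(rl_loss(logp_prior, logp_theta, R, rc.sigma))
        if all(r == 0.0 for r in rewards):
            consecutive_invalid += 1
            if consecutive_invalid > rc.max_consecutive_invalid:
                raise DivergenceError("too many consecutive all-invalid RL batches")
        else:
            consecutive_invalid = 0
        batch_loss = losses[0]
        for l in losses[1:]:
            batch_loss = batch_loss + l
        batch_loss = batch_loss * (1.0 / len(losses))
        opt.zero_grad()
        batch_loss.backward()
        opt.step()
        state.step = step + 1
        mean_r = float(np.mean(rewards))
        state.reward_trace.append(mean_r)
        if log is not None:
            log({"step": step, "mean_reward": mean_r, "loss": float(batch_loss.data)})
    return state


def sample_sequence(
    model: DualStreamGenerator,
    constraint_vector: np.ndarray,
    tok_vocab: TokenVocabulary,
    fg_names: Sequence[str],
    ctx: ProteinContext | None = None,
    temperature: float = 1.0,
    seed: int = 0,
) -> tuple[DualSequence, int, str]:
    """Sample one molecule and return its full dual sequence.

    ``prompt_len`` marks the first position after ``[BOS]``: the RL objective
    sums log-probabilities over the SMILES body (the freely generated
    region).
    """
    from .model import generate_sequences

    smiles_list, seqs, prompt_lens = generate_sequences(
        model, constraint_vector, tok_vocab, fg_names, ctx=ctx,
        n_samples=1, mode="temperature", temperature=temperature, seed=seed,
    )
    return seqs[0], prompt_lens[0], smiles_list[0]


def kl_to_prior(
    policy: DualStreamGenerator,
    prior: DualStreamGenerator,
    probe: Sequence[DualSequence],
    ctx: ProteinContext | None = None,
) -> float:
    """Mean per-position KL(policy || prior) over a probe set of sequences."""
    total, count = 0.0, 0
    for seq in probe:
        lp_pol, _ = policy.forward(seq.text_ids[None], seq.numeric_values[None], ctx=ctx)
        lp_pri, _ = prior.forward(seq.text_ids[None], seq.numeric_values[None], ctx=ctx)
        p = np.exp(log_softmax(lp_pol, axis=-1).data[0])
        logq = log_softmax(lp_pri, axis=-1).data[0]
        logp = np.log(np.maximum(p, 1e-300))
        kl = (p * (logp - logq)).sum(axis=-1)  # per position
        total += float(kl.sum())
        count += kl.shape[0]
    return total / max(count, 1)
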