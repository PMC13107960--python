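"""Shared fixtures.

The expensive artifacts (memorization training run, RL run) are session-scoped
so the property tests and the acceptance tests measure the same computation
instead of repeating it.
"""

from __future__ import annotations

import numpy as np
import pytest

import nummolgen as nmg
from nummolgen.model import ModelConfig
from nummolgen.synthetic import SurrogateScorer, make_memorization_fixture
from nummolgen.training import (
    RLConfig,
    TrainConfig,
    pretrain,
    reward,
    rl_finetune,
    sample_sequence,
)


@pytest.fixture(scope="session")
def fg_vocab():
    return nmg.build_vocabulary()


@pytest.fixture(scope="session")
def fg_names(fg_vocab):
    return [t.name for t in fg_vocab]


@pytest.fixture(scope="session")
def corpus100(fg_vocab):
    """100 synthetic drug-like molecules with annotations."""
    return nmg.generate_corpus(nmg.CorpusSpec(n_molecules=100, seed=0), fg_vocab)


@pytest.fixture(scope="session")
def corpus1000(fg_vocab):
    """1,000-molecule corpus for the codec round-trip suite."""
    return nmg.generate_corpus(nmg.CorpusSpec(n_molecules=1000, seed=0), fg_vocab)


@pytest.fixture(scope="session")
def memo_fixture(fg_vocab):
    """32 molecules with pairwise-distinct count vectors."""
    return make_memorization_fixture(fg_vocab, n=32, seed=0)


@pytest.fixture(scope="session")
def memo_tok_vocab(memo_fixture, fg_vocab):
    return nmg.build_token_vocabulary(memo_fixture, fg_vocab)


@pytest.fixture(scope="session")
def memo_seqs(memo_fixture, memo_tok_vocab):
    return [nmg.encode_dual(a, memo_tok_vocab) for a in memo_fixture]


@pytest.fixture(scope="session")
def memorized(memo_fixture, memo_tok_vocab, memo_seqs):
    """A 2-layer, d=64 model trained to memorize the 32-molecule corpus.

    Returns (model, history); the training run itself is part of what the
    suite verifies (loss contract, reconstruction, determinism of the
    convergence path).
    """
    max_len = max(len(s) for s in memo_seqs)
    config = ModelConfig(vocab_size=memo_tok_vocab.size, max_len=max_len + 16)
    model, history = pretrain(
        memo_seqs,
        config,
        memo_tok_vocab,
        TrainConfig(epochs=500, lr=3e-3, batch_size=32, loss_target=0.005),
        seed=0,
    )
    return model, history


@pytest.fixture(scope="session")
def scorer():
    return SurrogateScorer()


def mean_sampled_reward(model, constraints, tok_vocab, fg_names, scorer,
                        n=64, seed=123):
    """Monte-Carlo mean reward of a policy under the constraint distribution."""
    rng = np.random.default_rng(seed)
    rewards = []
    for _ in range(n):
        cvec = constraints[int(rng.integers(len(constraints)))]
        _, _, smiles = sample_sequence(
            model, cvec, tok_vocab, fg_names,
            temperature=1.0, seed=int(rng.integers(2**31 - 1)),
        )
        scores = scorer.score(smiles)
        rewards.append(0.0 if scores is None else reward(*scores))
    return float(np.mean(rewards))


@pytest.fixture(scope="session")
def rl_bundle(memo_fixture, memo_tok_vocab, memo_seqs, fg_names, scorer):
    """RL improvement run from a partially trained prior.

    A prior stopped early (composite loss ~0.15) still derails often, so its
    mean reward is low; sixty augmented-likelihood steps against the
    deterministic surrogate scorer sharpen it.  Returns a dict with the
    prior/posterior reward estimates and the reward trace.
    """
    max_len = max(len(s) for s in memo_seqs)
    config = ModelConfig(vocab_size=memo_tok_vocab.size, max_len=max_len + 16)
    prior, _ = pretrain(
        memo_seqs,
        config,
        memo_tok_vocab,
        TrainConfig(epochs=120, lr=3e-3, batch_size=32, loss_target=0.08),
        seed=0,
    )
    constraints = [a.count_vector() for a in memo_fixture]
    prior_mean = mean_sampled_reward(
        prior, constraints, memo_tok_vocab, fg_names, scorer
    )
    policy = prior.copy()
    state = rl_finetune(
        policy,
        memo_tok_vocab,
        fg_names,
        scorer,
        constraints,
        RLConfig(steps=60, batch_size=8, sigma=20.0, lr=2e-4, temperature=1.0),
        seed=0,
    )
    return {
        "prior": prior,
        "policy": policy,
        "state": state,
        "prior_mean_reward": prior_mean,
        "constraints": constraints,
    }
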