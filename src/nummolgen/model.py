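"""The number-aware molecular transformer.

Architecture overview
---------------------

Token ids are embedded as ``E_text`` (learned token + absolute position
embeddings).  The aligned numeric stream enters through a three-channel
numerical embedding: (i) *raw injection* — the scalar ``n`` added to every
coordinate of the token embedding, (ii) a *sign embedding* — a learned row per
sign in {-1, 0, +1}, and (iii) a *soft magnitude quantization* — ``|n|`` is
pushed through two small GELU MLPs whose softmax outputs mix two learnable
K-bin embedding tables, the second scaled by a learnable factor ``lambda``.
The fused stream is ``E_fusion = E_text + (n·1 + e_sign + e_mag)``.

Each decoder block runs causal self-attention over both streams with *shared*
projection weights, isolates the numerical increment as
``H_diff = Attn(E_fusion) - Attn(E_text)``, and updates

* the text stream as a standard decoder block:
  ``T' = Norm(T + H_text)`` then ``T'' = Norm(T' + SwiGLU(T'))``;
* the fusion stream with the differential signal:
  ``E' = Norm(F + H_diff)`` then ``F'' = Norm(E' + SwiGLU(E'))``
  (normalization gains and SwiGLU weights shared with the text stream).

Dual heads read the fusion stream: next-token logits and a scalar regression
of the *next* position's numeric value.  With the numerical channel disabled
the two streams coincide, every ``H_diff`` is exactly zero, and the model is
bitwise a plain decoder over the text stream.

Optional pocket conditioning: per-residue protein embeddings (produced
externally by a frozen protein language model) enter once, before the decoder
stack, through a cross-attention layer whose output projection is
zero-initialized — so conditioning is an exact no-op at initialization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, embedding, log_softmax, rms_norm, softmax
from .exceptions import (
    ConfigurationError,
    ContractViolation,
    NumericDomainError,
)
from .sequence import (
    BOS,
    EOS,
    NONE,
    NUM,
    SEP,
    DualSequence,
    TokenVocabulary,
    fg_token,
)

NEG_INF = -1e30


@dataclass
class ModelConfig:
    """Hyperparameters of the network."""

    vocab_size: int
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    K_bins: int = 16
    mag_hidden: int = 32
    max_len: int = 256
    dropout: float = 0.0
    pocket_dim: int = 0  # 0 disables pocket conditioning
    d_ff: int | None = None  # SwiGLU hidden width; default 2*d_model

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ConfigurationError("d_model must be divisible by n_heads")
        for name in ("vocab_size", "d_model", "n_layers", "n_heads", "K_bins", "max_len"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.K_bins < 2:
            raise ConfigurationError("K_bins must be at least 2")
        if self.d_ff is None:
            self.d_ff = 2 * self.d_model


@dataclass
class ProteinContext:
    """Precomputed per-residue pocket embeddings (rows = residues)."""

    embeddings: np.ndarray  # (L_p, d_p)
    pocket_id: str = ""

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] < 1:
            raise ConfigurationError("pocket embeddings must be a (L_p, d_p) matrix")
        if not np.all(np.isfinite(self.embeddings)):
            raise NumericDomainError("pocket embeddings contain non-finite entries")


@dataclass
class NumericalEmbeddingParams:
    """All learnable tensors of the numerical embedding module."""

    sign_table: Tensor  # (3, d): rows for sign -1, 0, +1
    q_W1: Tensor  # (1, h)
    q_b1: Tensor  # (h,)
    q_W2: Tensor  # (h, K)
    q_b2: Tensor  # (K,)
    r_W1: Tensor
    r_b1: Tensor
    r_W2: Tensor
    r_b2: Tensor
    v_q: Tensor  # (K, d)
    v_r: Tensor  # (K, d)
    lam: Tensor  # scalar

    @staticmethod
    def init(d: int, K: int, h: int, rng: np.random.Generator) -> "NumericalEmbeddingParams":
        p = lambda shape, s=0.02: ad.parameter(shape, rng, s)
        return NumericalEmbeddingParams(
            sign_table=p((3, d)),
            q_W1=p((1, h), 0.5), q_b1=Tensor(np.zeros(h), requires_grad=True),
            q_W2=p((h, K), 0.5), q_b2=Tensor(np.zeros(K), requires_grad=True),
            r_W1=p((1, h), 0.5), r_b1=Tensor(np.zeros(h), requires_grad=True),
            r_W2=p((h, K), 0.5), r_b2=Tensor(np.zeros(K), requires_grad=True),
            v_q=p((K, d)),
            v_r=p((K, d)),
            lam=Tensor(np.array(1.0), requires_grad=True),
        )

    def tensors(self) -> list[Tensor]:
        return [getattr(self, f.name) for f in self.__dataclass_fields__.values()]  # type: ignore[attr-defined]


def _bin_weights(mag: np.ndarray, W1: Tensor, b1: Tensor, W2: Tensor, b2: Tensor) -> Tensor:
    """Soft bin assignment: softmax(W2 · GELU(W1·|n| + b1) + b2)."""
    x = Tensor(mag[..., None])  # (..., 1)
    hidden = (x @ W1 + b1).gelu()
    return softmax(hidden @ W2 + b2, axis=-1)


def numerical_embedding(
    E_text: Tensor,
    numeric_values: np.ndarray,
    params: NumericalEmbeddingParams,
) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    """The three-channel scalar embedding.

    Returns ``(e_raw, e_sign, e_mag, e_num)``, each with the shape of
    ``E_text``; ``e_num = e_raw + e_sign + e_mag``.
    """
    n = np.asarray(numeric_values, dtype=np.float64)
    if not np.all(np.isfinite(n)):
        raise NumericDomainError("numeric stream contains non-finite values")
    if n.shape != E_text.shape[:-1]:
        raise ContractViolation(
            f"numeric stream shape {n.shape} does not match embeddings {E_text.shape[:-1]}"
        )
    e_raw = E_text + Tensor(n[..., None])
    sign_idx = (np.sign(n) + 1).astype(np.int64)  # -1/0/+1 -> 0/1/2
    e_sign = embedding(params.sign_table, sign_idx)
    mag = np.abs(n)
    p_q = _bin_weights(mag, params.q_W1, params.q_b1, params.q_W2, params.q_b2)
    p_r = _bin_weights(mag, params.r_W1, params.r_b1, params.r_W2, params.r_b2)
    e_mag = p_q @ params.v_q + params.lam * (p_r @ params.v_r)
    e_num = e_raw + e_sign + e_mag
    return e_raw, e_sign, e_mag, e_num


@dataclass
class _Block:
    Wq: Tensor
    Wk: Tensor
    Wv: Tensor
    Wo: Tensor
    g_attn: Tensor  # norm gain after attention residual
    g_ffn: Tensor  # norm gain after SwiGLU residual
    W_gate: Tensor  # (d, d_ff) SwiGLU gate projection
    W_val: Tensor  # (d, d_ff) SwiGLU value projection
    W_out: Tensor  # (d_ff, d)

    @staticmethod
    def init(d: int, d_ff: int, rng: np.random.Generator) -> "_Block":
        p = lambda shape, s: ad.parameter(shape, rng, s)
        s = 0.02
        return _Block(
            Wq=p((d, d), s), Wk=p((d, d), s), Wv=p((d, d), s), Wo=p((d, d), s),
            g_attn=Tensor(np.ones(d), requires_grad=True),
            g_ffn=Tensor(np.ones(d), requires_grad=True),
            W_gate=p((d, d_ff), s), W_val=p((d, d_ff), s), W_out=p((d_ff, d), s),
        )

    def tensors(self) -> list[Tensor]:
        return [self.Wq, self.Wk, self.Wv, self.Wo, self.g_attn, self.g_ffn,
                self.W_gate, self.W_val, self.W_out]


@dataclass
class _CrossAttn:
    Wq: Tensor  # (d, d)
    Wk: Tensor  # (d_p, d)
    Wv: Tensor  # (d_p, d)
    Wo: Tensor  # (d, d), zero-initialized gate
    g_q: Tensor  # query pre-norm gain

    @staticmethod
    def init(d: int, d_p: int, rng: np.random.Generator) -> "_CrossAttn":
        p = lambda shape, s: ad.parameter(shape, rng, s)
        return _CrossAttn(
            Wq=p((d, d), 0.02), Wk=p((d_p, d), 0.02), Wv=p((d_p, d), 0.02),
            Wo=Tensor(np.zeros((d, d)), requires_grad=True),
            g_q=Tensor(np.ones(d), requires_grad=True),
        )

    def tensors(self) -> list[Tensor]:
        return [self.Wq, self.Wk, self.Wv, self.Wo, self.g_q]


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    B, L, d = x.shape
    return x.reshape(B, L, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    B, H, L, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, L, H * dh)


def _attend(
    q_src: Tensor, kv_src: Tensor,
    Wq: Tensor, Wk: Tensor, Wv: Tensor, Wo: Tensor,
    n_heads: int, bias: np.ndarray | None,
) -> Tensor:
    """Multi-head scaled dot-product attention; ``bias`` is added to logits."""
    d = Wq.shape[1]
    scale = 1.0 / math.sqrt(d // n_heads)
    q = _split_heads((q_src @ Wq) * scale, n_heads)  # scale pre-split: smaller array
    k = _split_heads(kv_src @ Wk, n_heads)
    v = _split_heads(kv_src @ Wv, n_heads)
    att = softmax(q @ k.swapaxes(-1, -2), axis=-1, bias=bias)
    return _merge_heads(att @ v) @ Wo


def _swiglu(x: Tensor, W_gate: Tensor, W_val: Tensor, W_out: Tensor) -> Tensor:
    gate = x @ W_gate
    return (gate * gate.sigmoid() * (x @ W_val)) @ W_out  # SiLU(gate) * value


def causal_bias(L: int) -> np.ndarray:
    bias = np.zeros((L, L))
    bias[np.triu_indices(L, k=1)] = NEG_INF
    return bias


class DualStreamGenerator:
    """Autoregressive dual-stream generator over dual sequences."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, V = config.d_model, config.vocab_size
        p = lambda shape, s=0.02: ad.parameter(shape, rng, s)
        self.tok_table = p((V, d))
        self.pos_table = p((config.max_len, d))
        self.num_params = NumericalEmbeddingParams.init(d, config.K_bins, config.mag_hidden, rng)
        self.blocks = [_Block.init(d, config.d_ff, rng) for _ in range(config.n_layers)]
        self.cross: _CrossAttn | None = (
            _CrossAttn.init(d, config.pocket_dim, rng) if config.pocket_dim > 0 else None
        )
        self.g_final = Tensor(np.ones(d), requires_grad=True)
        self.W_tok_head = p((d, V))
        self.b_tok_head = Tensor(np.zeros(V), requires_grad=True)
        self.W_num_head = p((d, 1))
        self.b_num_head = Tensor(np.zeros(1), requires_grad=True)

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        out = [self.tok_table, self.pos_table]
        out += self.num_params.tensors()
        for b in self.blocks:
            out += b.tensors()
        if self.cross is not None:
            out += self.cross.tensors()
        out += [self.g_final, self.W_tok_head, self.b_tok_head,
                self.W_num_head, self.b_num_head]
        return out

    def copy(self) -> "DualStreamGenerator":
        clone = DualStreamGenerator(self.config, seed=0)
        for a, b in zip(clone.parameters(), self.parameters()):
            a.data = b.data.copy()
        return clone

    # -- forward -----------------------------------------------------------
    def embed(self, text_ids: np.ndarray, numeric: np.ndarray,
              numeric_channel: bool = True) -> tuple[Tensor, Tensor]:
        """Return (E_text, E_fusion) for a (B, L) batch."""
        B, L = text_ids.shape
        if L > self.config.max_len:
            raise ContractViolation(
                f"sequence length {L} exceeds max_len={self.config.max_len}"
            )
        E_text = embedding(self.tok_table, text_ids) + self.pos_table[:L]
        if not numeric_channel:
            return E_text, E_text
        _, e_sign, e_mag, _ = numerical_embedding(E_text, numeric, self.num_params)
        increment = Tensor(np.asarray(numeric, dtype=np.float64)[..., None]) + e_sign + e_mag
        return E_text, E_text + increment

    def _cross_attend(self, F: Tensor, ctx: ProteinContext) -> Tensor:
        assert self.cross is not None
        if ctx.embeddings.shape[1] != self.config.pocket_dim:
            raise ConfigurationError(
                f"pocket embedding dim {ctx.embeddings.shape[1]} != configured "
                f"pocket_dim {self.config.pocket_dim}"
            )
        c = self.cross
        B = F.shape[0]
        kv = Tensor(np.broadcast_to(ctx.embeddings, (B,) + ctx.embeddings.shape).copy())
        q_in = rms_norm(F, c.g_q)
        return F + _attend(q_in, kv, c.Wq, c.Wk, c.Wv, c.Wo,
                           self.config.n_heads, bias=None)

    def forward(
        self,
        text_ids: np.ndarray,
        numeric: np.ndarray,
        ctx: ProteinContext | None = None,
        numeric_channel: bool = True,
        return_streams: bool = False,
    ):
        """Run the decoder stack.

        Returns ``(token_logits, numeric_preds)`` — logits of shape
        ``(B, L, V)`` and per-position scalar predictions of the *next*
        position's numeric value, shape ``(B, L)``.  With
        ``return_streams=True`` also returns the per-layer ``H_diff`` arrays.
        """
        text_ids = np.asarray(text_ids, dtype=np.int64)
        numeric = np.asarray(numeric, dtype=np.float64)
        if text_ids.ndim == 1:
            text_ids, numeric = text_ids[None], numeric[None]
        B, L = text_ids.shape
        T, F = self.embed(text_ids, numeric, numeric_channel=numeric_channel)
        if ctx is not None:
            if self.cross is None:
                raise ConfigurationError("model was built without pocket conditioning")
            F = self._cross_attend(F, ctx)
        bias = causal_bias(L)
        h_diffs: list[np.ndarray] = []
        cfg = self.config
        single_stream = not numeric_channel and ctx is None
        for blk in self.blocks:
            H_text = _attend(T, T, blk.Wq, blk.Wk, blk.Wv, blk.Wo, cfg.n_heads, bias)
            if single_stream:
                # F is T bitwise: recomputing attention gives the identical
                # array, so H_diff vanishes exactly and one update suffices.
                H_fusion = _attend(F, F, blk.Wq, blk.Wk, blk.Wv, blk.Wo, cfg.n_heads, bias)
                h_diffs.append(H_fusion.data - H_text.data)
                A = rms_norm(T + H_text, blk.g_attn)
                T = rms_norm(A + _swiglu(A, blk.W_gate, blk.W_val, blk.W_out), blk.g_ffn)
                F = T
                continue
            H_fusion = _attend(F, F, blk.Wq, blk.Wk, blk.Wv, blk.Wo, cfg.n_heads, bias)
            H_diff = H_fusion - H_text
            h_diffs.append(H_diff.data)
            A_T = rms_norm(T + H_text, blk.g_attn)
            T = rms_norm(A_T + _swiglu(A_T, blk.W_gate, blk.W_val, blk.W_out), blk.g_ffn)
            E_prime = rms_norm(F + H_diff, blk.g_attn)
            F = rms_norm(E_prime + _swiglu(E_prime, blk.W_gate, blk.W_val, blk.W_out), blk.g_ffn)
        out = rms_norm(F, self.g_final)
        token_logits = out @ self.W_tok_head + self.b_tok_head
        numeric_preds = (out @ self.W_num_head + self.b_num_head).reshape(B, L)
        if not (np.all(np.isfinite(token_logits.data)) and np.all(np.isfinite(numeric_preds.data))):
            raise NumericDomainError("non-finite model outputs")
        if return_streams:
            return token_logits, numeric_preds, h_diffs
        return token_logits, numeric_preds

    # -- generation --------------------------------------------------------
    def generate(
        self,
        constraint_vector: Sequence[int],
        tok_vocab: TokenVocabulary,
        fg_names: Sequence[str],
        ctx: ProteinContext | None = None,
        n_samples: int = 1,
        mode: str = "greedy",
        temperature: float = 1.0,
        top_k: int = 0,
        seed: int = 0,
        max_instance_atoms: int = 8,
    ) -> list[str]:
        """Sample SMILES under a functional-group count constraint.

        The constraint header is teacher-forced as the prompt: group and
        ``[NUM]`` tokens (numeric stream filled from ``constraint_vector``)
        and ``[NONE]`` for absent groups.  Instance position tokens for
        present groups are sampled from the model under a grammar mask (only
        position tokens or ``[SEP]``; the number of ``[SEP]`` is pinned to the
        target count).  After ``[BOS]``, SMILES tokens are sampled freely
        until ``[EOS]`` or the length cap.  Returned strings are raw model
        output; validity is checked downstream.
        """
        smiles, _, _ = generate_sequences(
            self, constraint_vector, tok_vocab, fg_names, ctx=ctx,
            n_samples=n_samples, mode=mode, temperature=temperature,
            top_k=top_k, seed=seed, max_instance_atoms=max_instance_atoms,
        )
        return smiles

    def _next_logits(self, text: list[int], numeric: list[float],
                     ctx: ProteinContext | None) -> np.ndarray:
        logits, _ = self.forward(np.array([text]), np.array([numeric]), ctx=ctx)
        return logits.data[0, -1]

    def sequence_log_prob(
        self,
        seq: DualSequence,
        prompt_len: int,
        ctx: ProteinContext | None = None,
    ) -> Tensor:
        """Differentiable log-probability of tokens from ``prompt_len`` on."""
        text = seq.text_ids[None]
        logits, _ = self.forward(text, seq.numeric_values[None], ctx=ctx)
        logp = log_softmax(logits, axis=-1)
        L = text.shape[1]
        rows = np.arange(prompt_len - 1, L - 1)
        targets = text[0, prompt_len:]
        picked = logp[0, rows, targets]
        return picked.sum()

    # -- checkpointing -----------------------------------------------------
    def _named_arrays(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.data for i, p in enumerate(self.parameters())}

    def save(self, path: str | Path, tok_vocab: TokenVocabulary,
             fg_vocab_hash: str, extra: dict | None = None) -> None:
        meta = {
            "config": asdict(self.config),
            "token_vocab": list(tok_vocab.id_to_token),
            "fg_vocab_hash": fg_vocab_hash,
            "extra": extra or {},
        }
        arrays = self._named_arrays()
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path, expected_fg_hash: str | None = None
             ) -> tuple["DualStreamGenerator", TokenVocabulary, dict]:
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            cfg = ModelConfig(**meta["config"])
            model = cls(cfg, seed=0)
            for i, p in enumerate(model.parameters()):
                p.data = npz[f"param_{i}"].astype(ad.DTYPE)
        if expected_fg_hash is not None and meta["fg_vocab_hash"] != expected_fg_hash:
            raise ConfigurationError(
                "checkpoint was trained with a different functional-group vocabulary "
                f"(hash {meta['fg_vocab_hash'][:12]}… != {expected_fg_hash[:12]}…)"
            )
        tok_vocab = TokenVocabulary(meta["token_vocab"])
        return model, tok_vocab, meta


def add_pocket_conditioning(
    model: DualStreamGenerator, pocket_dim: int, seed: int = 0
) -> DualStreamGenerator:
    """Extend an unconditional model with a (zero-gated) cross-attention layer.

    All existing weights are copied; the new cross-attention output projection
    is zero-initialized, so the extended model's unconditional behaviour — and
    its conditional behaviour at step 0 of fine-tuning — is bitwise unchanged.
    """
    if pocket_dim <= 0:
        raise ConfigurationError("pocket_dim must be positive")
    from dataclasses import replace

    cfg = replace(model.config, pocket_dim=pocket_dim)
    new = DualStreamGenerator(cfg, seed=seed)
    new.tok_table.data = model.tok_table.data.copy()
    new.pos_table.data = model.pos_table.data.copy()
    for dst, src in zip(new.num_params.tensors(), model.num_params.tensors()):
        dst.data = src.data.copy()
    for dst_blk, src_blk in zip(new.blocks, model.blocks):
        for dst, src in zip(dst_blk.tensors(), src_blk.tensors()):
            dst.data = src.data.copy()
    new.g_final.data = model.g_final.data.copy()
    new.W_tok_head.data = model.W_tok_head.data.copy()
    new.b_tok_head.data = model.b_tok_head.data.copy()
    new.W_num_head.data = model.W_num_head.data.copy()
    new.b_num_head.data = model.b_num_head.data.copy()
    return new


def generate_sequences(
    model: DualStreamGenerator,
    constraint_vector: Sequence[int],
    tok_vocab: TokenVocabulary,
    fg_names: Sequence[str],
    ctx: ProteinContext | None = None,
    n_samples: int = 1,
    mode: str = "greedy",
    temperature: float = 1.0,
    top_k: int = 0,
    seed: int = 0,
    max_instance_atoms: int = 8,
) -> tuple[list[str], list[DualSequence], list[int]]:
    """Constraint-prompted sampling, returning full sequences.

    Returns ``(smiles, sequences, prompt_lens)`` where ``prompt_lens[i]`` is
    the index of the first position after ``[BOS]`` (the start of the freely
    generated SMILES body).
    """
    constraint = np.asarray(constraint_vector, dtype=np.int64)
    if constraint.shape[0] != len(fg_names):
        raise ContractViolation(
            f"constraint vector length {constraint.shape[0]} != vocabulary size {len(fg_names)}"
        )
    if np.any(constraint < 0):
        raise ContractViolation("constraint counts must be non-negative")
    rng = np.random.default_rng(seed)
    pos_ids = set(tok_vocab.position_token_ids())
    smiles_ids = set(tok_vocab.smiles_token_ids())
    sep_id, none_id = tok_vocab.id(SEP), tok_vocab.id(NONE)
    bos_id, eos_id, num_id = tok_vocab.id(BOS), tok_vocab.id(EOS), tok_vocab.id(NUM)
    all_smiles: list[str] = []
    all_seqs: list[DualSequence] = []
    all_prompt_lens: list[int] = []
    for _ in range(n_samples):
        text: list[int] = []
        numeric: list[float] = []

        def push(tid: int, val: float = 0.0):
            text.append(tid)
            numeric.append(val)

        def next_id(allowed: set[int]) -> int:
            logits = model._next_logits(text, numeric, ctx)
            masked = np.full_like(logits, NEG_INF)
            idx = np.fromiter(allowed, dtype=np.int64)
            masked[idx] = logits[idx]
            return _sample(masked, rng, mode, temperature, top_k)

        cap = model.config.max_len

        def room() -> int:
            return cap - len(text)

        for c in constraint:  # teacher-forced constraint-summary prefix
            push(num_id, float(c))
        for i, name in enumerate(fg_names):
            if room() <= 4:  # leave space for [BOS] and at least one token
                break
            push(tok_vocab.id(fg_token(name)))
            push(num_id, float(constraint[i]))
            if constraint[i] == 0:
                push(none_id)
                continue
            for _ in range(int(constraint[i])):
                if room() <= 3:
                    break
                n_atoms = 0
                while True:
                    # sampled instances are capped both per-instance and by
                    # the remaining length budget; a clipped header yields an
                    # off-template prompt whose molecule is simply filtered
                    # downstream as invalid
                    if n_atoms >= max_instance_atoms or room() <= 3:
                        tid = sep_id
                    else:
                        allowed = set(pos_ids) if n_atoms == 0 else pos_ids | {sep_id}
                        tid = next_id(allowed)
                    push(tid)
                    if tid == sep_id:
                        break
                    n_atoms += 1
        push(bos_id)
        prompt_len = len(text)
        while len(text) < model.config.max_len:
            tid = next_id(smiles_ids | {eos_id})
            push(tid)
            if tid == eos_id:
                break
        seq = DualSequence(np.array(text), np.array(numeric))
        end = text.index(eos_id, prompt_len) if eos_id in text[prompt_len:] else len(text)
        all_smiles.append("".join(tok_vocab.token(t) for t in text[prompt_len:end]))
        all_seqs.append(seq)
        all_prompt_lens.append(prompt_len)
    return all_smiles, all_seqs, all_prompt_lens


def plain_decoder_forward(model: DualStreamGenerator, text_ids: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """A standard single-stream decoder using the model's own weights.

    Reference implementation for the reduction property: with the numerical
    channel disabled, :meth:`DualStreamGenerator.forward` must match this bitwise.
    """
    text_ids = np.asarray(text_ids, dtype=np.int64)
    if text_ids.ndim == 1:
        text_ids = text_ids[None]
    B, L = text_ids.shape
    cfg = model.config
    X = embedding(model.tok_table, text_ids) + model.pos_table[:L]
    bias = causal_bias(L)
    for blk in model.blocks:
        H = _attend(X, X, blk.Wq, blk.Wk, blk.Wv, blk.Wo, cfg.n_heads, bias)
        A = rms_norm(X + H, blk.g_attn)
        X = rms_norm(A + _swiglu(A, blk.W_gate, blk.W_val, blk.W_out), blk.g_ffn)
    out = rms_norm(X, model.g_final)
    logits = out @ model.W_tok_head + model.b_tok_head
    preds = (out @ model.W_num_head + model.b_num_head).reshape(B, L)
    return logits.data, preds.data


def _sample(logits: np.ndarray, rng: np.random.Generator, mode: str,
            temperature: float, top_k: int) -> int:
    if mode == "greedy" or (mode == "temperature" and temperature <= 1e-8):
        return int(np.argmax(logits))
    if mode == "temperature":
        scaled = logits / temperature
    elif mode == "top-k":
        if top_k <= 0:
            raise ConfigurationError("top-k sampling requires top_k > 0")
        kth = np.sort(logits)[-top_k]
        scaled = np.where(logits >= kth, logits, NEG_INF)
    else:
        raise ConfigurationError(f"unknown sampling mode {mode!r}")
    scaled = scaled - scaled.max()
    probs = np.exp(scaled)
    probs /= probs.sum()
    return int(rng.choice(len(probs), p=probs))
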