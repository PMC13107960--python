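"""Text/numeric dual-sequence codec.

A molecule annotation is serialized into two strictly aligned streams of equal
length: a *text* stream of discrete tokens and a *numeric* stream of real
values.  The numeric stream is zero everywhere except at ``[NUM]`` positions,
where it carries the (raw, unnormalized) count of the corresponding functional
group — counts enter the model as scalars, not as digit tokens.

Template, fixed and versioned::

    [NUM] x T                               (constraint-summary prefix: the
                                             full count vector, one numeric
                                             slot per group in vocab order)
    [FG:name] [NUM] <p:i> <p:j> ... [SEP]   (repeated once per instance)
    [FG:name] [NUM] [NONE]                  (absent group)
    ...
    [BOS] smiles-token ... [EOS]

``<p:k>`` are atom-position tokens (0-based canonical-SMILES atom order);
``[SEP]`` closes each instance.  The SMILES body uses regex-based atom-level
tokens.

The prefix exists for conditioning: during constrained generation the whole
count vector is teacher-forced before any token is sampled, so instance
positions and the SMILES body are always generated with the complete
constraint in context.  The per-group ``[NUM]`` slots repeat each group's
count next to its positions and are the numeric head's training targets.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotate import FGVocabulary, MoleculeAnnotation
from .exceptions import (
    ContractViolation,
    EncodingError,
    MalformedSequenceError,
    TruncationError,
    VocabularyError,
)

PAD, BOS, EOS, NUM, SEP, NONE = "[PAD]", "[BOS]", "[EOS]", "[NUM]", "[SEP]", "[NONE]"
SPECIALS = (PAD, BOS, EOS, NUM, SEP, NONE)

# Atom-level SMILES tokenization (bracket atoms, two-letter elements, ring
# closures and bonds as single tokens) — the de facto standard regex.
_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|@@|%\d{2}|[BCNOSPFIbcnosp]|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|\d)"
)


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into atom-level tokens (lossless)."""
    tokens = _SMILES_TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise EncodingError(f"SMILES {smiles!r} contains untokenizable characters")
    return tokens


def fg_token(name: str) -> str:
    return f"[FG:{name}]"


def pos_token(index: int) -> str:
    return f"<p:{index}>"


class TokenVocabulary:
    """Bijective token <-> id map with a fixed, deterministic layout.

    Ids are dense ``0..V-1`` with ``[PAD]`` at 0; specials come first, then
    one ``[FG:name]`` token per functional-group type (vocabulary order), then
    position tokens ``<p:0>..<p:max_atoms-1>``, then SMILES tokens in
    lexicographic order.
    """

    def __init__(self, tokens: Sequence[str]):
        if not tokens or tokens[0] != PAD:
            raise VocabularyError("token list must start with [PAD]")
        missing = [s for s in SPECIALS if s not in tokens]
        if missing:
            raise VocabularyError(f"missing special tokens: {missing}")
        if len(set(tokens)) != len(tokens):
            raise VocabularyError("duplicate tokens in vocabulary")
        self.id_to_token: tuple[str, ...] = tuple(tokens)
        self.token_to_id: dict[str, int] = {t: i for i, t in enumerate(tokens)}

    @property
    def size(self) -> int:
        return len(self.id_to_token)

    def __len__(self) -> int:
        return len(self.id_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def id(self, token: str) -> int:
        try:
            return self.token_to_id[token]
        except KeyError:
            raise EncodingError(f"token {token!r} not in vocabulary") from None

    def token(self, idx: int) -> str:
        return self.id_to_token[idx]

    # token-class views used by grammar-constrained generation
    def position_token_ids(self) -> list[int]:
        return [i for i, t in enumerate(self.id_to_token) if t.startswith("<p:")]

    def smiles_token_ids(self) -> list[int]:
        reserved = set(SPECIALS)
        return [
            i
            for i, t in enumerate(self.id_to_token)
            if t not in reserved and not t.startswith("<p:") and not t.startswith("[FG:")
        ]

    def to_json(self) -> str:
        return json.dumps(list(self.id_to_token))

    @classmethod
    def from_json(cls, payload: str) -> "TokenVocabulary":
        return cls(json.loads(payload))


def build_token_vocabulary(
    annotations: Iterable[MoleculeAnnotation],
    fg_vocab: FGVocabulary,
    min_position_tokens: int = 0,
) -> TokenVocabulary:
    """Assemble the token vocabulary for a corpus of annotations.

    Position tokens cover ``0..max_atoms-1`` where ``max_atoms`` is the
    largest atom count seen in the corpus (or ``min_position_tokens`` if
    larger, so vocabularies can be padded for forward compatibility).
    """
    annotations = list(annotations)
    if not annotations:
        raise VocabularyError("cannot build a token vocabulary from an empty corpus")
    from rdkit import Chem

    max_atoms = min_position_tokens
    smiles_tokens: set[str] = set()
    for ann in annotations:
        toks = tokenize_smiles(ann.canonical_smiles)
        smiles_tokens.update(toks)
        # full atom count, not just featured atoms: position coverage must
        # extend to every atom of the largest molecule
        mol = Chem.MolFromSmiles(ann.canonical_smiles)
        if mol is not None:
            max_atoms = max(max_atoms, mol.GetNumAtoms())
    tokens = list(SPECIALS)
    tokens += [fg_token(t.name) for t in fg_vocab]
    tokens += [pos_token(i) for i in range(max_atoms)]
    tokens += sorted(smiles_tokens)
    return TokenVocabulary(tokens)


@dataclass
class DualSequence:
    """Aligned text-token-id and numeric-value streams of equal length."""

    text_ids: np.ndarray  # int64, shape (L,)
    numeric_values: np.ndarray  # float64, shape (L,)

    def __post_init__(self):
        self.text_ids = np.asarray(self.text_ids, dtype=np.int64)
        self.numeric_values = np.asarray(self.numeric_values, dtype=np.float64)
        if self.text_ids.shape != self.numeric_values.shape:
            raise ContractViolation(
                f"stream lengths differ: {self.text_ids.shape} vs {self.numeric_values.shape}"
            )

    def __len__(self) -> int:
        return int(self.text_ids.shape[0])

    def tokens(self, vocab: TokenVocabulary) -> list[str]:
        return [vocab.token(int(i)) for i in self.text_ids]


def encode_dual(annotation: MoleculeAnnotation, tok_vocab: TokenVocabulary) -> DualSequence:
    """Serialize an annotation into its dual sequence.

    The numeric stream holds each group's count at its ``[NUM]`` slots (both
    in the constraint-summary prefix and in its per-group block) and 0.0
    everywhere else; both streams always have equal length.
    """
    text: list[str] = []
    numeric: list[float] = []

    def emit(token: str, value: float = 0.0):
        text.append(token)
        numeric.append(value)

    for t in annotation.triplets:  # constraint-summary prefix
        emit(NUM, float(t.count))
    for t in annotation.triplets:
        emit(fg_token(t.fg_type.name))
        emit(NUM, float(t.count))
        if t.count == 0:
            emit(NONE)
        else:
            for inst in t.instances:
                for _, idx in inst.atoms:
                    emit(pos_token(idx))
                emit(SEP)
    emit(BOS)
    for tok in tokenize_smiles(annotation.canonical_smiles):
        emit(tok)
    emit(EOS)

    ids = np.array([tok_vocab.id(t) for t in text], dtype=np.int64)
    return DualSequence(text_ids=ids, numeric_values=np.array(numeric))


def decode_smiles(seq: DualSequence, tok_vocab: TokenVocabulary) -> str:
    """Extract the SMILES string between ``[BOS]`` and ``[EOS]``."""
    ids = seq.text_ids.tolist()
    bos, eos = tok_vocab.id(BOS), tok_vocab.id(EOS)
    if bos not in ids:
        raise MalformedSequenceError("sequence has no [BOS]")
    start = ids.index(bos)
    if eos not in ids[start:]:
        raise MalformedSequenceError("sequence has no [EOS] after [BOS]")
    end = ids.index(eos, start)
    return "".join(tok_vocab.token(i) for i in ids[start + 1 : end])


def decode_constraints(
    seq: DualSequence, fg_vocab: FGVocabulary, tok_vocab: TokenVocabulary
) -> np.ndarray:
    """Recover the count vector from the constraint-summary prefix.

    The first ``T`` positions (``T`` = vocabulary size) must all be ``[NUM]``
    tokens; their numeric values, rounded to the nearest integer, are the
    count vector.
    """
    T = fg_vocab.size
    ids = seq.text_ids
    if len(ids) < T:
        raise MalformedSequenceError(
            f"sequence of length {len(ids)} is shorter than the {T}-slot prefix"
        )
    num_id = tok_vocab.id(NUM)
    if not np.all(ids[:T] == num_id):
        raise MalformedSequenceError(
            "constraint-summary prefix is not a run of [NUM] tokens"
        )
    counts = np.rint(seq.numeric_values[:T]).astype(np.int64)
    if np.any(counts < 0):
        raise MalformedSequenceError("negative count in numeric stream")
    return counts


def pad_batch(
    seqs: Sequence[DualSequence], max_len: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-pad sequences to ``max_len``.

    Returns ``(text, numeric, mask)`` with shapes ``(B, max_len)``; ``mask``
    is True at real positions.  Over-length sequences raise
    :class:`TruncationError` — never silent truncation.
    """
    if not seqs:
        raise ContractViolation("empty batch")
    for s in seqs:
        if len(s) > max_len:
            raise TruncationError(f"sequence of length {len(s)} exceeds max_len={max_len}")
    B = len(seqs)
    text = np.zeros((B, max_len), dtype=np.int64)  # [PAD] id is 0
    numeric = np.zeros((B, max_len), dtype=np.float64)
    mask = np.zeros((B, max_len), dtype=bool)
    for b, s in enumerate(seqs):
        L = len(s)
        text[b, :L] = s.text_ids
        numeric[b, :L] = s.numeric_values
        mask[b, :L] = True
    return text, numeric, mask


def unpad_batch(
    text: np.ndarray, numeric: np.ndarray, mask: np.ndarray
) -> list[DualSequence]:
    out = []
    for b in range(text.shape[0]):
        L = int(mask[b].sum())
        out.append(DualSequence(text_ids=text[b, :L], numeric_values=numeric[b, :L]))
    return out


# ---------------------------------------------------------------------------
# JSONL serialization of encoded datasets


def write_dual_sequences(
    seqs: Iterable[DualSequence], tok_vocab: TokenVocabulary, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(
                json.dumps(
                    {
                        "text_tokens": s.tokens(tok_vocab),
                        "numeric_values": s.numeric_values.tolist(),
                    }
                )
                + "\n"
            )


def read_dual_sequences(path: str | Path, tok_vocab: TokenVocabulary) -> list[DualSequence]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            ids = np.array([tok_vocab.id(t) for t in rec["text_tokens"]], dtype=np.int64)
            out.append(DualSequence(text_ids=ids, numeric_values=np.array(rec["numeric_values"])))
    return out
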