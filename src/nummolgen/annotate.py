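"""Functional-group annotation of molecules.

A molecule is described by the triplet set ``{(type, count, positions)}``: for
every functional-group type in a fixed vocabulary, how many times it occurs and
which atoms each occurrence covers.  Types are defined by SMARTS substructure
patterns; the default vocabulary enumerates the 27 named pharmacophoric feature
definitions shipped with RDKit (donors, acceptors, ionizable groups, Zn
binders, aromatic rings, hydrophobes), giving a 27-dimensional count space.

Counts are numbers of *distinct atom sets* matched by the pattern: symmetric
matches over the same atoms are counted once.  Absent groups carry count 0 and
an empty instance list, so every annotation has one triplet per vocabulary
entry and annotations of different molecules align entrywise.
"""

from __future__ import annotations

import csv
import functools
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import ChemicalFeatures

from .exceptions import (
    MoleculeTooLargeError,
    SmilesParseError,
    VocabularyError,
)

RDLogger.DisableLog("rdApp.*")

#: Default cap on molecule size; larger molecules are rejected at annotation
#: time so that downstream position tokens stay within a fixed range.
DEFAULT_MAX_ATOMS = 128


def canonicalize_smiles(smiles: str) -> str:
    """Return the RDKit-canonical SMILES for ``smiles``.

    Idempotent: canonicalizing an already-canonical string returns it
    unchanged.  Raises :class:`SmilesParseError` on invalid input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles), "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return Chem.MolToSmiles(mol)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse ``smiles`` (raising :class:`SmilesParseError`) with implicit Hs."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


@dataclass(frozen=True)
class FGType:
    """One functional-group type: a named SMARTS pattern with a dense index."""

    name: str
    pattern: str
    vocab_index: int

    def __post_init__(self):
        if Chem.MolFromSmarts(self.pattern) is None:
            raise VocabularyError(
                f"pattern for {self.name!r} does not parse as SMARTS: {self.pattern!r}"
            )


@dataclass(frozen=True)
class FGInstance:
    """One occurrence of a functional group: the atoms it covers.

    ``atoms`` is an ordered list of ``(element_symbol, atom_index)`` pairs with
    0-based indices over the canonical-SMILES atom order.
    """

    atoms: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("FGInstance must cover at least one atom")
        idx = [i for _, i in self.atoms]
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate atom indices in instance: {idx}")

    @property
    def atom_indices(self) -> tuple[int, ...]:
        return tuple(i for _, i in self.atoms)


@dataclass(frozen=True)
class FGTriplet:
    """(type, count, positions) for one group in one molecule."""

    fg_type: FGType
    count: int
    instances: tuple[FGInstance, ...]

    def __post_init__(self):
        if self.count != len(self.instances):
            raise ValueError(
                f"count {self.count} != number of instances {len(self.instances)}"
            )


class FGVocabulary:
    """Ordered, deterministic collection of :class:`FGType`.

    Equality of two vocabularies (and checkpoint compatibility) is decided by
    :meth:`content_hash` over the ordered (name, pattern) pairs.
    """

    def __init__(self, types: Sequence[FGType]):
        if not types:
            raise VocabularyError("functional-group vocabulary must be non-empty")
        names = [t.name for t in types]
        if len(set(names)) != len(names):
            raise VocabularyError("duplicate functional-group names")
        for i, t in enumerate(types):
            if t.vocab_index != i:
                raise VocabularyError(
                    f"vocab_index of {t.name!r} is {t.vocab_index}, expected {i}"
                )
        self.types: tuple[FGType, ...] = tuple(types)

    @property
    def size(self) -> int:
        return len(self.types)

    def __len__(self) -> int:
        return len(self.types)

    def __iter__(self) -> Iterator[FGType]:
        return iter(self.types)

    def __getitem__(self, i: int) -> FGType:
        return self.types[i]

    def index_of(self, name: str) -> int:
        for t in self.types:
            if t.name == name:
                return t.vocab_index
        raise KeyError(name)

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for t in self.types:
            h.update(t.name.encode())
            h.update(b"\x00")
            h.update(t.pattern.encode())
            h.update(b"\x00")
        return h.hexdigest()


@dataclass
class MoleculeAnnotation:
    """Canonical SMILES plus one :class:`FGTriplet` per vocabulary entry."""

    canonical_smiles: str
    triplets: tuple[FGTriplet, ...] = field(default_factory=tuple)

    def count_vector(self) -> np.ndarray:
        return count_vector(self)


def _default_fdef_path() -> str:
    return os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")


def build_vocabulary(source: str | Path = "default") -> FGVocabulary:
    """Build a functional-group vocabulary from a feature-definition file.

    ``source`` is either the literal string ``"default"`` (RDKit's base
    pharmacophoric feature definitions; 27 entries) or a path to an ``.fdef``
    file.  Entries are enumerated in file order under ``Family.TypeName``
    names, so the vocabulary is deterministic given the source.
    """
    path = _default_fdef_path() if source == "default" else str(source)
    if not os.path.exists(path):
        raise VocabularyError(f"feature definition file not found: {path}")
    try:
        factory = ChemicalFeatures.BuildFeatureFactory(path)
    except Exception as exc:  # RDKit raises bare RuntimeError with line info
        raise VocabularyError(f"malformed feature definition file {path}: {exc}") from exc
    defs = factory.GetFeatureDefs()  # insertion-ordered: file order
    if not defs:
        raise VocabularyError(f"feature definition file {path} defines no features")
    types = [
        FGType(name=name, pattern=smarts, vocab_index=i)
        for i, (name, smarts) in enumerate(defs.items())
    ]
    return FGVocabulary(types)


@functools.lru_cache(maxsize=512)
def _compiled(pattern: str) -> Chem.Mol:
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise VocabularyError(f"pattern does not parse as SMARTS: {pattern!r}")
    return query


def _match_atom_sets(mol: Chem.Mol, pattern: str) -> list[tuple[int, ...]]:
    """Distinct atom-index tuples matched by ``pattern``, deduplicated.

    Matches that cover the same atom set (symmetric/automorphic duplicates)
    collapse to one instance; the surviving tuple is the sorted atom list and
    instances are ordered lexicographically for determinism.
    """
    query = _compiled(pattern)
    raw = mol.GetSubstructMatches(query, uniquify=True, maxMatches=10000)
    seen: dict[frozenset[int], tuple[int, ...]] = {}
    for match in raw:
        key = frozenset(match)
        if key not in seen:
            seen[key] = tuple(sorted(match))
    return sorted(seen.values())


def annotate_molecule(
    smiles: str,
    vocab: FGVocabulary,
    max_atoms: int = DEFAULT_MAX_ATOMS,
) -> MoleculeAnnotation:
    """Annotate ``smiles`` with one triplet per vocabulary entry.

    The molecule is canonicalized first; atom indices refer to the
    canonical-SMILES atom order (0-based).  Raises
    :class:`MoleculeTooLargeError` if the molecule has more than ``max_atoms``
    heavy atoms.
    """
    canonical = canonicalize_smiles(smiles)
    mol = mol_from_smiles(canonical)
    n_atoms = mol.GetNumAtoms()
    if n_atoms > max_atoms:
        raise MoleculeTooLargeError(
            f"molecule has {n_atoms} atoms, cap is {max_atoms}: {canonical}"
        )
    triplets = []
    for fg in vocab:
        atom_sets = _match_atom_sets(mol, fg.pattern)
        instances = tuple(
            FGInstance(
                atoms=tuple(
                    (mol.GetAtomWithIdx(i).GetSymbol(), i) for i in atom_set
                )
            )
            for atom_set in atom_sets
        )
        triplets.append(FGTriplet(fg_type=fg, count=len(instances), instances=instances))
    return MoleculeAnnotation(canonical_smiles=canonical, triplets=tuple(triplets))


def count_vector(annotation: MoleculeAnnotation) -> np.ndarray:
    """Flatten an annotation into its integer count vector (vocab order)."""
    return np.array([t.count for t in annotation.triplets], dtype=np.int64)


# ---------------------------------------------------------------------------
# I/O


def read_smiles(path: str | Path, smiles_column: str = "smiles") -> list[str]:
    """Read SMILES from a text file (one per line) or a CSV with a column."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or smiles_column not in reader.fieldnames:
                raise VocabularyError(
                    f"CSV {path} has no {smiles_column!r} column"
                )
            return [row[smiles_column].strip() for row in reader if row[smiles_column].strip()]
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def annotation_to_record(annotation: MoleculeAnnotation) -> dict:
    return {
        "canonical_smiles": annotation.canonical_smiles,
        "triplets": [
            {
                "type": t.fg_type.name,
                "count": t.count,
                "instances": [[[el, idx] for el, idx in inst.atoms] for inst in t.instances],
            }
            for t in annotation.triplets
        ],
    }


def record_to_annotation(record: dict, vocab: FGVocabulary) -> MoleculeAnnotation:
    by_name = {t["type"]: t for t in record["triplets"]}
    triplets = []
    for fg in vocab:
        t = by_name[fg.name]
        instances = tuple(
            FGInstance(atoms=tuple((el, int(idx)) for el, idx in inst))
            for inst in t["instances"]
        )
        triplets.append(FGTriplet(fg_type=fg, count=int(t["count"]), instances=instances))
    return MoleculeAnnotation(
        canonical_smiles=record["canonical_smiles"], triplets=tuple(triplets)
    )


def write_annotations(annotations: Iterable[MoleculeAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            fh.write(json.dumps(annotation_to_record(ann)) + "\n")


def read_annotations(path: str | Path, vocab: FGVocabulary) -> list[MoleculeAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(record_to_annotation(json.loads(line), vocab))
    return out
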