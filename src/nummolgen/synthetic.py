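"""Deterministic synthetic fixtures: corpora, pocket embeddings, scorer.

The corpus generator enumerates scaffold x substituent combinations of small
drug-like fragments, chosen so functional-group counts span roughly 0-4 per
group across the corpus — enough range to exercise the numeric channel.  It
emulates the shape of a drug-like SMILES corpus (sizes, group-count spread),
not the property distributions of any real library.

Pocket "embeddings" are seeded unit-scale Gaussian matrices standing in for
per-residue protein-language-model features (synthetic; no protein encoder is
run).  The surrogate docking scorer is a fixed smooth function of molecular
descriptors, deterministic per molecule, so reward computations are exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, QED

from .annotate import (
    FGVocabulary,
    MoleculeAnnotation,
    annotate_molecule,
)
from .evaluation import sa_normalized
from .exceptions import ConfigurationError, CorpusShortfallError
from .model import ProteinContext

# Aromatic/aliphatic cores with one or two substitution sites.  Kept small so
# encoded sequences stay short; {R} marks a substitution point.
DEFAULT_SCAFFOLDS = (
    "c1ccc({R})cc1",          # benzene
    "c1ccc({R})nc1",          # pyridine
    "c1cc({R})c[nH]1",        # pyrrole (aromatic 5-ring)
    "C1CCC({R})CC1",          # cyclohexane
    "c1cc({R})cc({R})c1",     # 1,3-disubstituted benzene
    "c1ccc({R})c({R})c1",     # 1,2-disubstituted benzene
    "C1CC({R})CC({R})C1",     # 1,3-disubstituted cyclohexane
    "C({R})C{R}",             # short chain, two sites
)

# Substituents covering donors, acceptors, acids, bases, halogens,
# hydrophobes and small rings.
DEFAULT_SUBSTITUENTS = (
    "O",            # hydroxyl
    "N",            # primary amine
    "C(=O)O",       # carboxylic acid
    "C(=O)N",       # amide
    "C#N",          # nitrile
    "S",            # thiol
    "Cl",
    "F",
    "OC",           # methyl ether
    "CO",           # hydroxymethyl
    "C(C)C",        # isopropyl
    "C(C)(C)C",     # tert-butyl
    "[N+](=O)[O-]", # nitro
    "C(=O)C",       # methyl ketone
    "c1ccccc1",     # phenyl
    "NC(=N)N",      # guanidine
    "Br",
    "S(N)(=O)=O",   # sulfonamide
    "C(=O)OC",      # methyl ester
    "C=C",          # vinyl
    "I",
    "OCC",          # ethoxy
)


@dataclass
class CorpusSpec:
    """Recipe for a deterministic synthetic SMILES corpus."""

    n_molecules: int = 100
    scaffolds: tuple[str, ...] = DEFAULT_SCAFFOLDS
    substituents: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    max_atoms: int = 48
    seed: int = 0

    def __post_init__(self):
        if not self.scaffolds or not self.substituents:
            raise ConfigurationError("scaffold and substituent sets must be non-empty")
        if self.n_molecules <= 0:
            raise ConfigurationError("n_molecules must be positive")


def _enumerate_smiles(spec: CorpusSpec) -> list[str]:
    """All valid, size-capped, canonical scaffold x substituent products."""
    seen: set[str] = set()
    ordered: list[str] = []
    for scaffold in spec.scaffolds:
        n_sites = scaffold.count("{R}")
        for sub in spec.substituents:
            candidate = scaffold.replace("{R}", sub)
            mol = Chem.MolFromSmiles(candidate)
            if mol is None or mol.GetNumAtoms() > spec.max_atoms:
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical not in seen:
                seen.add(canonical)
                ordered.append(canonical)
        if n_sites == 2:
            # mixed pairs on two-site scaffolds widen the count range
            for sub_a in spec.substituents:
                for sub_b in spec.substituents:
                    candidate = scaffold.replace("{R}", sub_a, 1).replace("{R}", sub_b, 1)
                    mol = Chem.MolFromSmiles(candidate)
                    if mol is None or mol.GetNumAtoms() > spec.max_atoms:
                        continue
                    canonical = Chem.MolToSmiles(mol)
                    if canonical not in seen:
                        seen.add(canonical)
                        ordered.append(canonical)
    return ordered


def generate_corpus(
    spec: CorpusSpec,
    vocab: FGVocabulary,
) -> tuple[list[str], list[MoleculeAnnotation]]:
    """Deterministic corpus of ``spec.n_molecules`` distinct canonical SMILES.

    Every emitted molecule is valid, within the atom cap, and annotated.
    Raises :class:`CorpusShortfallError` if the spec cannot yield enough
    distinct molecules.
    """
    pool = _enumerate_smiles(spec)
    if len(pool) < spec.n_molecules:
        raise CorpusShortfallError(
            f"spec yields only {len(pool)} distinct molecules, "
            f"{spec.n_molecules} requested"
        )
    rng = np.random.default_rng(spec.seed)
    chosen_idx = rng.permutation(len(pool))[: spec.n_molecules]
    smiles = [pool[i] for i in sorted(chosen_idx)]
    annotations = [annotate_molecule(s, vocab, max_atoms=spec.max_atoms) for s in smiles]
    return smiles, annotations


def select_unique_constraint_subset(
    annotations: Sequence[MoleculeAnnotation], n: int
) -> list[MoleculeAnnotation]:
    """First ``n`` annotations with pairwise-distinct count vectors.

    Count-only prompts cannot distinguish molecules that share a count
    vector, so memorization fixtures use a collision-free subset.
    """
    seen: set[tuple[int, ...]] = set()
    out: list[MoleculeAnnotation] = []
    for ann in annotations:
        key = tuple(int(t.count) for t in ann.triplets)
        if key not in seen:
            seen.add(key)
            out.append(ann)
        if len(out) == n:
            return out
    raise CorpusShortfallError(
        f"only {len(out)} distinct count vectors available, {n} requested"
    )


def make_memorization_fixture(
    vocab: FGVocabulary,
    n: int = 32,
    seed: int = 0,
) -> list[MoleculeAnnotation]:
    """A corpus built to be exactly memorizable by a tiny model.

    Count-conditioned greedy decoding can only reproduce a molecule whose
    count vector is unique in the corpus (the constraint prompt is the sole
    identity signal), so molecules sharing a vector are filtered out.  Among
    the eligible molecules the ``n`` with the shortest encodings are kept,
    interleaved across the sorted list so the fixture spans different
    scaffolds rather than one homologous series.
    """
    pool = _enumerate_smiles(CorpusSpec(n_molecules=1, seed=seed))
    annotations = [annotate_molecule(s, vocab) for s in pool]
    eligible = select_unique_constraint_subset(
        annotations,
        n=len({tuple(t.count for t in a.triplets) for a in annotations}),
    )
    if len(eligible) < n:
        raise CorpusShortfallError(
            f"only {len(eligible)} memorizable molecules available, {n} requested"
        )
    # shortest encodings first: header length scales with instance counts
    def encoded_length(a: MoleculeAnnotation) -> int:
        header = sum(
            3 if t.count == 0 else 2 + sum(len(i.atoms) + 1 for i in t.instances)
            for t in a.triplets
        )
        return header + len(a.canonical_smiles)

    eligible.sort(key=lambda a: (encoded_length(a), a.canonical_smiles))
    shortest = eligible[: 2 * n]  # keep sequences short: attention is O(L^2)
    picked = shortest[::2] if len(shortest) >= 2 * n else shortest[:n]
    return picked[:n]


def generate_pocket_fixtures(
    n_pockets: int, L_p: int, d_p: int, seed: int = 0
) -> list[ProteinContext]:
    """Seeded unit-scale Gaussian pocket matrices (synthetic stand-ins)."""
    if n_pockets <= 0 or L_p <= 0 or d_p <= 0:
        raise ConfigurationError("pocket fixture dimensions must be positive")
    rng = np.random.default_rng(seed)
    return [
        ProteinContext(
            embeddings=rng.normal(0.0, 1.0, size=(L_p, d_p)) / np.sqrt(d_p),
            pocket_id=f"pocket_{i:03d}",
        )
        for i in range(n_pockets)
    ]


def split_corpus(
    items: Sequence, ratios: tuple[float, float, float], seed: int = 0
) -> tuple[list, list, list]:
    """Disjoint, exhaustive train/val/test split with a seeded shuffle."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError(f"split ratios must sum to 1, got {ratios}")
    n = len(items)
    n_train = round(n * ratios[0])
    n_val = round(n * ratios[1])
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) <= 0:
        raise ConfigurationError(
            f"split of {n} items with ratios {ratios} leaves an empty part"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train : n_train + n_val]]
    test = [items[i] for i in order[n_train + n_val :]]
    return train, val, test


class SurrogateScorer:
    """Deterministic stand-in for a docking engine.

    The pseudo-docking score is a smooth function of heavy-atom count and
    ring count, negated and clipped to a realistic kcal/mol range, so larger
    ring-bearing molecules "bind" more strongly; QED and normalized SA are
    the real descriptors.  Same molecule -> same scores, bitwise.
    """

    def score(self, smiles: str) -> tuple[float, float, float] | None:
        mol = Chem.MolFromSmiles(smiles) if smiles else None
        if mol is None:
            return None
        n_heavy = mol.GetNumHeavyAtoms()
        n_rings = Chem.rdMolDescriptors.CalcNumRings(mol)
        logp = Crippen.MolLogP(mol)
        pseudo_dock = -(1.1 * np.sqrt(n_heavy) + 0.9 * n_rings + 0.15 * max(logp, 0.0))
        pseudo_dock = float(np.clip(pseudo_dock, -12.0, -0.5))
        return pseudo_dock, float(QED.qed(mol)), float(sa_normalized(mol))


def make_conditional_fixture(
    annotations: Sequence[MoleculeAnnotation],
    n_pockets: int = 4,
    L_p: int = 16,
    d_p: int = 32,
    seed: int = 0,
) -> tuple[list[ProteinContext], list[tuple[ProteinContext, MoleculeAnnotation]], dict[str, str]]:
    """Pair each pocket with one molecule family for the separability task.

    Families are defined by marker substructures; pocket i is paired only
    with molecules containing marker i, giving a learnable pocket-conditional
    signal.  Returns (pockets, pairs, family map pocket_id -> marker SMARTS).
    """
    markers = ["C(=O)O", "C#N", "Cl", "[N+](=O)[O-]"][:n_pockets]
    if len(markers) < n_pockets:
        raise ConfigurationError(f"at most {len(markers)} fixture families available")
    pockets = generate_pocket_fixtures(n_pockets, L_p, d_p, seed=seed)
    queries = [Chem.MolFromSmarts(m) for m in markers]
    pairs: list[tuple[ProteinContext, MoleculeAnnotation]] = []
    family: dict[str, str] = {}
    for pocket, marker, query in zip(pockets, markers, queries):
        family[pocket.pocket_id] = marker
        for ann in annotations:
            mol = Chem.MolFromSmiles(ann.canonical_smiles)
            # exclusive membership keeps families separable
            in_this = mol.HasSubstructMatch(query)
            in_other = any(
                mol.HasSubstructMatch(q) for q in queries if q is not query
            )
            if in_this and not in_other:
                pairs.append((pocket, ann))
    if not pairs:
        raise CorpusShortfallError("no molecules matched any fixture family")
    return pockets, pairs, family
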