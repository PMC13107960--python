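"""Quality and constraint-compliance metrics for generated molecules.

Quality: validity / uniqueness / novelty, Lipinski rule-of-five compliance
(reported both as the all-five pass fraction and as the mean number of rules
satisfied on the 0-5 scale — the literature uses the same name for both),
QED, normalized synthetic accessibility, pairwise Tanimoto diversity, and the
structure-based success rate (Vina dock < -8.18, QED > 0.25, SA > 0.59, all
strict).

Constraint compliance against target count vectors over the functional-group
vocabulary: mean squared error of counts, exact match rate (EMR: every group
count equals its target) and fuzzy match rate (FMR: every count within +/-3).
Invalid molecules count as failures for EMR/FMR and are excluded from MSE
with their count reported.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, Descriptors, Lipinski as RDLipinski, QED
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import TanimotoSimilarity

from .annotate import FGVocabulary, annotate_molecule, count_vector
from .exceptions import (
    ContractViolation,
    ScoringError,
    UndefinedMetricError,
)

sys.path.insert(0, os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit's contributed synthetic-accessibility scorer)

FUZZY_TOLERANCE = 3
SUCCESS_VINA, SUCCESS_QED, SUCCESS_SA = -8.18, 0.25, 0.59


@dataclass
class QualityReport:
    n_molecules: int
    validity: float
    uniqueness: float
    novelty: float
    lipinski_all5_fraction: float
    lipinski_mean_rules: float
    mean_qed: float
    mean_sa_norm: float
    diversity: float | None = None
    success_rate: float | None = None


@dataclass
class ConstraintReport:
    mse: float
    emr: float
    fmr: float
    n_invalid: int
    per_group_frequency_ratio: np.ndarray = field(repr=False, default=None)
    per_group_average_count: np.ndarray = field(repr=False, default=None)


def _valid_mols(smiles_list: Sequence[str]) -> list[tuple[str, Chem.Mol]]:
    out = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s) if isinstance(s, str) and s else None
        if mol is not None:
            out.append((Chem.MolToSmiles(mol), mol))
    return out


def validity(smiles_list: Sequence[str]) -> float:
    """Fraction of strings that parse into molecules."""
    if not smiles_list:
        raise UndefinedMetricError("validity of an empty set is undefined")
    return len(_valid_mols(smiles_list)) / len(smiles_list)


def uniqueness(valid_smiles: Sequence[str]) -> float:
    """Distinct canonical molecules / valid molecules."""
    mols = _valid_mols(valid_smiles)
    if not mols:
        raise UndefinedMetricError("uniqueness of an empty set is undefined")
    return len({c for c, _ in mols}) / len(mols)


def novelty(valid_smiles: Sequence[str], reference: Iterable[str]) -> float:
    """Fraction of distinct valid molecules absent from the reference set."""
    mols = _valid_mols(valid_smiles)
    if not mols:
        raise UndefinedMetricError("novelty of an empty set is undefined")
    ref = set(reference)
    distinct = {c for c, _ in mols}
    return sum(1 for c in distinct if c not in ref) / len(distinct)


def lipinski_rules(mol: Chem.Mol) -> int:
    """Number of rule-of-five criteria satisfied (0-5).

    Criteria (the five-rule variant standard in generative SBDD benchmarks):
    MW <= 500, H-bond donors <= 5, H-bond acceptors <= 10, logP <= 5,
    rotatable bonds <= 10.
    """
    rules = [
        Descriptors.MolWt(mol) <= 500,
        RDLipinski.NumHDonors(mol) <= 5,
        RDLipinski.NumHAcceptors(mol) <= 10,
        Crippen.MolLogP(mol) <= 5,
        RDLipinski.NumRotatableBonds(mol) <= 10,
    ]
    return int(sum(rules))


def lipinski_metrics(smiles_list: Sequence[str]) -> tuple[float, float]:
    """(fraction satisfying all 5 rules, mean rules satisfied)."""
    mols = _valid_mols(smiles_list)
    if not mols:
        raise UndefinedMetricError("Lipinski metrics of an empty set are undefined")
    counts = [lipinski_rules(m) for _, m in mols]
    return sum(c == 5 for c in counts) / len(counts), float(np.mean(counts))


def sa_normalized(mol: Chem.Mol) -> float:
    """Synthetic accessibility on [0, 1], higher = easier: (10 - raw) / 9."""
    return (10.0 - sascorer.calculateScore(mol)) / 9.0


def qed_and_sa(smiles_list: Sequence[str]) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-molecule QED and normalized SA; returns (qed, sa, n_failed)."""
    mols = _valid_mols(smiles_list)
    if not mols:
        raise UndefinedMetricError("QED/SA of an empty set is undefined")
    qeds, sas, failed = [], [], 0
    for _, m in mols:
        try:
            qeds.append(QED.qed(m))
            sas.append(sa_normalized(m))
        except Exception:
            failed += 1
    return np.array(qeds), np.array(sas), failed


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def diversity(smiles_list: Sequence[str]) -> float:
    """Mean pairwise Tanimoto distance on Morgan(r=2, 2048-bit) fingerprints."""
    mols = _valid_mols(smiles_list)
    if len(mols) < 2:
        raise UndefinedMetricError("diversity needs at least two valid molecules")
    fps = [_MORGAN.GetFingerprint(m) for _, m in mols]
    dists = []
    for i in range(len(fps)):
        for j in range(i + 1, len(fps)):
            dists.append(1.0 - TanimotoSimilarity(fps[i], fps[j]))
    return float(np.mean(dists))


def success_rate(records: Sequence[Mapping[str, float]]) -> float:
    """Fraction meeting Vina dock < -8.18, QED > 0.25, SA > 0.59 (all strict)."""
    if not records:
        raise UndefinedMetricError("success rate of an empty record set is undefined")
    n_ok = 0
    for rec in records:
        for key in ("vina_dock", "qed", "sa_norm"):
            if key not in rec:
                raise ScoringError(f"record missing field {key!r}: {dict(rec)!r}")
        if (
            rec["vina_dock"] < SUCCESS_VINA
            and rec["qed"] > SUCCESS_QED
            and rec["sa_norm"] > SUCCESS_SA
        ):
            n_ok += 1
    return n_ok / len(records)


def quality_report(
    smiles_list: Sequence[str],
    reference: Iterable[str] = (),
    scored_records: Sequence[Mapping[str, float]] | None = None,
) -> QualityReport:
    """Aggregate quality metrics for a generated set."""
    v = validity(smiles_list)
    valid = [c for c, _ in _valid_mols(smiles_list)]
    if not valid:
        raise UndefinedMetricError("no valid molecules to evaluate")
    uniq = uniqueness(valid)
    nov = novelty(valid, reference)
    lip_all5, lip_mean = lipinski_metrics(valid)
    qeds, sas, _ = qed_and_sa(valid)
    div = diversity(valid) if len(set(valid)) >= 2 else None
    sr = success_rate(scored_records) if scored_records else None
    return QualityReport(
        n_molecules=len(smiles_list),
        validity=v,
        uniqueness=uniq,
        novelty=nov,
        lipinski_all5_fraction=lip_all5,
        lipinski_mean_rules=lip_mean,
        mean_qed=float(qeds.mean()),
        mean_sa_norm=float(sas.mean()),
        diversity=div,
        success_rate=sr,
    )


def constraint_compliance(
    target_vectors: Sequence[np.ndarray],
    generated_smiles: Sequence[str],
    vocab: FGVocabulary,
) -> ConstraintReport:
    """Compare generated functional-group counts against their targets."""
    if len(target_vectors) != len(generated_smiles):
        raise ContractViolation(
            f"{len(target_vectors)} targets but {len(generated_smiles)} molecules"
        )
    if not generated_smiles:
        raise UndefinedMetricError("constraint compliance of an empty set is undefined")
    sq_errors = []
    exact, fuzzy, invalid = 0, 0, 0
    observed_vectors = []
    for target, smiles in zip(target_vectors, generated_smiles):
        target = np.asarray(target, dtype=np.int64)
        if target.shape[0] != vocab.size:
            raise ContractViolation(
                f"target vector length {target.shape[0]} != vocabulary size {vocab.size}"
            )
        try:
            ann = annotate_molecule(smiles, vocab)
        except Exception:
            invalid += 1  # counts as EMR/FMR failure, excluded from MSE
            continue
        observed = count_vector(ann)
        observed_vectors.append(observed)
        diff = observed - target
        sq_errors.append(float(np.mean(diff.astype(float) ** 2)))
        if np.all(diff == 0):
            exact += 1
        if np.all(np.abs(diff) <= FUZZY_TOLERANCE):
            fuzzy += 1
    n = len(generated_smiles)
    mse = float(np.mean(sq_errors)) if sq_errors else float("nan")
    obs = np.array(observed_vectors) if observed_vectors else np.zeros((0, vocab.size))
    freq = (obs > 0).mean(axis=0) if len(obs) else np.zeros(vocab.size)
    avg = obs.mean(axis=0) if len(obs) else np.zeros(vocab.size)
    return ConstraintReport(
        mse=mse,
        emr=exact / n,
        fmr=fuzzy / n,
        n_invalid=invalid,
        per_group_frequency_ratio=np.asarray(freq, dtype=float),
        per_group_average_count=np.asarray(avg, dtype=float),
    )


@dataclass
class FGProfile:
    """Per-group occurrence statistics of one molecule collection."""

    frequency_ratio: np.ndarray  # fraction of molecules with >= 1 instance
    average_count: np.ndarray  # mean count per molecule


def fg_profiles(
    molecule_sets: Mapping[str, Sequence[str]],
    vocab: FGVocabulary,
) -> dict[str, FGProfile]:
    """Frequency-ratio and average-count profiles for named collections."""
    out: dict[str, FGProfile] = {}
    for name, smiles_list in molecule_sets.items():
        if not smiles_list:
            raise UndefinedMetricError(f"collection {name!r} is empty")
        counts = np.array(
            [count_vector(annotate_molecule(s, vocab)) for s in smiles_list]
        )
        out[name] = FGProfile(
            frequency_ratio=(counts > 0).mean(axis=0),
            average_count=counts.mean(axis=0),
        )
    return out


def profile_mse(a: FGProfile, b: FGProfile, statistic: str = "frequency_ratio") -> float:
    """Mean squared difference of a per-group statistic between collections."""
    if statistic not in ("frequency_ratio", "average_count"):
        raise KeyError(statistic)
    xa, xb = getattr(a, statistic), getattr(b, statistic)
    return float(np.mean((xa - xb) ** 2))
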