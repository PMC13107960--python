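"""Pluggable molecule scorers for the RL reward.

The reward needs a (docking affinity, QED, normalized SA) triple per
molecule.  :class:`~nummolgen.synthetic.SurrogateScorer` is the deterministic
default used throughout the test pipeline; this module adds an adapter for a
real command-line docking engine for users who have one installed.  The
adapter is never exercised by the test suite.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import AllChem, QED

from .evaluation import sa_normalized
from .exceptions import ScoringError


class VinaDockingScorer:
    """Adapter around an AutoDock-Vina-compatible command-line binary.

    Requires a prepared receptor file and a search box.  Ligands are
    embedded with ETKDG and converted via openbabel.  QED and SA come from
    RDKit as usual.
    """

    def __init__(
        self,
        receptor_pdbqt: str | Path,
        center: tuple[float, float, float],
        box_size: tuple[float, float, float] = (20.0, 20.0, 20.0),
        vina_binary: str = "vina",
        exhaustiveness: int = 8,
    ):
        if shutil.which(vina_binary) is None:
            raise ScoringError(f"docking binary {vina_binary!r} not found on PATH")
        if shutil.which("obabel") is None:
            raise ScoringError("openbabel ('obabel') is required to prepare ligands")
        self.receptor = Path(receptor_pdbqt)
        if not self.receptor.exists():
            raise ScoringError(f"receptor file not found: {self.receptor}")
        self.center = center
        self.box_size = box_size
        self.vina_binary = vina_binary
        self.exhaustiveness = exhaustiveness

    def _dock(self, mol: Chem.Mol) -> float:
        mol = Chem.AddHs(mol)
        if AllChem.EmbedMolecule(mol, randomSeed=0) != 0:
            raise ScoringError("3D embedding failed")
        AllChem.MMFFOptimizeMolecule(mol)
        with tempfile.TemporaryDirectory() as tmp:
            sdf = Path(tmp) / "ligand.sdf"
            pdbqt = Path(tmp) / "ligand.pdbqt"
            out = Path(tmp) / "out.pdbqt"
            Chem.MolToMolFile(mol, str(sdf))
            subprocess.run(
                ["obabel", str(sdf), "-O", str(pdbqt)],
                check=True, capture_output=True,
            )
            cx, cy, cz = self.center
            sx, sy, sz = self.box_size
            result = subprocess.run(
                [
                    self.vina_binary,
                    "--receptor", str(self.receptor),
                    "--ligand", str(pdbqt),
                    "--out", str(out),
                    "--center_x", str(cx), "--center_y", str(cy), "--center_z", str(cz),
                    "--size_x", str(sx), "--size_y", str(sy), "--size_z", str(sz),
                    "--exhaustiveness", str(self.exhaustiveness),
                ],
                check=True, capture_output=True, text=True,
            )
        for line in result.stdout.splitlines():
            parts = line.split()
            if len(parts) >= 2 and parts[0] == "1":
                return float(parts[1])
        raise ScoringError("could not parse docking output")

    def score(self, smiles: str) -> tuple[float, float, float] | None:
        mol = Chem.MolFromSmiles(smiles) if smiles else None
        if mol is None:
            return None
        return self._dock(mol), float(QED.qed(mol)), float(sa_normalized(mol))
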