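"""Descriptor representations: MACCS keys, ECFP4/6, drug-likeness properties.

Each representation of the whole compound set is a :class:`DescriptorBlock`
(an n x d matrix tagged binary or continuous). External descriptor blocks —
e.g. learned bioactivity signatures computed elsewhere — plug in through
:func:`register_external_block` and flow through the continuous path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, MACCSkeys, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator

from chemmultiverse.curation import SmilesParseError

#: Column order of the drug-likeness block.
DRUGLIKENESS_COLUMNS = ("MW", "cLogP", "TPSA", "HBD", "HBA", "RB")

MACCS_WIDTH = 166
ECFP_WIDTH = 2048


@dataclass
class DescriptorBlock:
    """One named representation of all compounds.

    ``kind`` is ``binary`` (fingerprint bits) or ``continuous``; binary
    blocks feed the Tanimoto path downstream, continuous blocks the
    standardized-Euclidean path.
    """

    name: str
    matrix: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.kind not in {"binary", "continuous"}:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.matrix.ndim != 2:
            raise ValueError("descriptor matrix must be 2-D")
        if self.kind == "binary" and not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("binary block contains values other than 0/1")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def compute_maccs(smiles: str) -> np.ndarray:
    """166-bit MACCS key vector (key k at position k-1)."""
    fp = MACCSkeys.GenMACCSKeys(_mol(smiles))
    bits = np.zeros(167, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return bits[1:]  # RDKit bit 0 is a placeholder; keys are 1..166


def compute_ecfp(smiles: str, diameter: int = 4) -> np.ndarray:
    """Folded 2048-bit extended-connectivity fingerprint.

    ``diameter`` is 4 or 6 (atom environments of radius 2 or 3).
    """
    if diameter not in (4, 6):
        raise ValueError("diameter must be 4 or 6")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=diameter // 2, fpSize=ECFP_WIDTH)
    fp = gen.GetFingerprint(_mol(smiles))
    bits = np.zeros(ECFP_WIDTH, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return bits


def compute_druglikeness(smiles: str) -> np.ndarray:
    """Six pharmaceutical-relevance properties: MW, cLogP, TPSA, HBD, HBA, RB.

    Counts (HBD/HBA/RB) are non-negative integers; the rotatable-bond count
    uses the strict definition (non-ring single bonds between non-terminal
    heavy atoms, amide C-N excluded).
    """
    mol = _mol(smiles)
    return np.array(
        [
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            rdMolDescriptors.CalcTPSA(mol),
            rdMolDescriptors.CalcNumHBD(mol),
            rdMolDescriptors.CalcNumHBA(mol),
            rdMolDescriptors.CalcNumRotatableBonds(
                mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
            ),
        ],
        dtype=float,
    )


def compute_block(smiles_list: Sequence[str], name: str) -> DescriptorBlock:
    """Compute a named block (maccs | ecfp4 | ecfp6 | druglikeness) for all compounds."""
    if name == "maccs":
        rows = [compute_maccs(s) for s in smiles_list]
        return DescriptorBlock(name=name, matrix=np.vstack(rows), kind="binary")
    if name in {"ecfp4", "ecfp6"}:
        diameter = int(name[-1])
        rows = [compute_ecfp(s, diameter) for s in smiles_list]
        return DescriptorBlock(name=name, matrix=np.vstack(rows), kind="binary")
    if name == "druglikeness":
        rows = [compute_druglikeness(s) for s in smiles_list]
        return DescriptorBlock(name=name, matrix=np.vstack(rows), kind="continuous")
    raise ValueError(f"unknown descriptor {name!r}")


def register_external_block(name: str, matrix: np.ndarray, n_compounds: int) -> DescriptorBlock:
    """Adapt an externally computed n x d matrix as a continuous block.

    The row count must equal the curated compound count; the width is free
    (learned signature vectors are commonly 128-dimensional but any d works).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != n_compounds:
        raise ValueError(
            f"external block {name!r} has {matrix.shape[0] if matrix.ndim == 2 else '?'} rows, "
            f"expected {n_compounds}"
        )
    return DescriptorBlock(name=f"external:{name}", matrix=matrix, kind="continuous")
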