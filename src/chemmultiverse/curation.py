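"""SMILES standardization pipeline producing one canonical SMILES per compound.

The protocol follows the MolVS lineage as implemented in RDKit's
``rdMolStandardize``: an element screen, iterative normalization of
functional-group and charge-separation patterns, neutralization, largest
covalent fragment selection, reionization, and canonical tautomer selection,
followed by canonical SMILES writing and duplicate elimination. The map is a
fixpoint: standardizing an already-standardized SMILES returns it unchanged.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

from chemmultiverse.dataio import ActivityMatrix, RawDataset

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

#: Drug-like element superset used when no explicit list is configured.
DEFAULT_ALLOWED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

STEP_NAMES = (
    "screen",
    "normalize",
    "uncharge",
    "largest_fragment",
    "reionize",
    "tautomer",
    "canonicalize",
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass
class CurationConfig:
    allowed_elements: frozenset[str] = DEFAULT_ALLOWED_ELEMENTS
    max_normalization_iterations: int = 200
    enable_tautomer: bool = True

    def __post_init__(self) -> None:
        self.allowed_elements = frozenset(self.allowed_elements)
        if not self.allowed_elements:
            raise ValueError("allowed_elements must be non-empty")
        if self.max_normalization_iterations < 1:
            raise ValueError("max_normalization_iterations must be >= 1")


@dataclass
class MoleculeRecord:
    """One compound's raw and curated SMILES with status flags.

    ``status`` is ``ok`` iff ``canonical_smiles`` is set; other states record
    why the compound was rejected.
    """

    id: str
    input_smiles: str
    canonical_smiles: str | None = None
    status: str = "ok"
    applied_steps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.status in {"ok", "unparseable", "disallowed_element", "duplicate_removed"}
        unknown = set(self.applied_steps) - set(STEP_NAMES)
        assert not unknown, f"unknown curation steps: {unknown}"


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def screen_elements(smiles: str, config: CurationConfig | None = None) -> bool:
    """True iff every atom's element is in the configured allowed set.

    Unparseable SMILES raise :class:`SmilesParseError` rather than returning
    False — a syntax failure is not an element rejection.
    """
    config = config or CurationConfig()
    mol = _parse(smiles)
    return all(atom.GetSymbol() in config.allowed_elements for atom in mol.GetAtoms())


def _normalizer(config: CurationConfig) -> rdMolStandardize.Normalizer:
    params = rdMolStandardize.CleanupParameters()
    params.maxRestarts = config.max_normalization_iterations
    return rdMolStandardize.NormalizerFromParams(params)


def standardize(
    smiles: str, config: CurationConfig | None = None
) -> tuple[str, list[str]]:
    """Standardize one SMILES; returns (canonical_smiles, applied_steps).

    Step order: normalize (iterated to a fixpoint or the iteration cap) ->
    uncharge -> largest covalent fragment by heavy-atom count -> reionize ->
    canonical tautomer (if enabled) -> canonical SMILES writer. A step is
    recorded in ``applied_steps`` only when it changed the structure, so an
    already-standard input reports no structural change.
    """
    config = config or CurationConfig()
    mol = _parse(smiles)
    applied: list[str] = []

    def run(step: str, fn) -> None:
        nonlocal mol
        before = Chem.MolToSmiles(mol)
        mol = fn(mol)
        if Chem.MolToSmiles(mol) != before:
            applied.append(step)

    run("normalize", _normalizer(config).normalize)
    # force=True neutralizes even in the presence of counterions (the salt
    # is dropped by the next step anyway)
    run("uncharge", rdMolStandardize.Uncharger(force=True).uncharge)
    run("largest_fragment", rdMolStandardize.LargestFragmentChooser().choose)
    run("reionize", rdMolStandardize.Reionizer().reionize)
    if config.enable_tautomer:
        run("tautomer", rdMolStandardize.TautomerEnumerator().Canonicalize)
    applied.append("canonicalize")
    return Chem.MolToSmiles(mol), applied


def deduplicate(records: list[MoleculeRecord]) -> list[MoleculeRecord]:
    """Mark later repeats of each canonical SMILES as ``duplicate_removed``.

    The first occurrence is retained; activities of removed duplicates are
    dropped by the caller, not merged.
    """
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for rec in records:
        if rec.status == "ok" and rec.canonical_smiles in seen:
            rec = MoleculeRecord(
                id=rec.id,
                input_smiles=rec.input_smiles,
                canonical_smiles=None,
                status="duplicate_removed",
                applied_steps=rec.applied_steps,
            )
        elif rec.status == "ok":
            seen.add(rec.canonical_smiles)
        out.append(rec)
    return out


def curate_dataset(
    raw: RawDataset, config: CurationConfig | None = None
) -> tuple[list[MoleculeRecord], ActivityMatrix]:
    """Run the full pipeline: parse -> element screen -> standardize -> dedup.

    Returns every input record (with its status) plus the activity matrix
    restricted to the surviving (status ``ok``) rows, row-aligned. Raises if
    no compound survives. Per-category rejection counts are logged.
    """
    config = config or CurationConfig()
    records: list[MoleculeRecord] = []
    for rid, smi in raw.records:
        try:
            allowed = screen_elements(smi, config)
        except SmilesParseError:
            records.append(MoleculeRecord(id=rid, input_smiles=smi, canonical_smiles=None,
                                          status="unparseable"))
            continue
        if not allowed:
            records.append(MoleculeRecord(id=rid, input_smiles=smi, canonical_smiles=None,
                                          status="disallowed_element",
                                          applied_steps=["screen"]))
            continue
        canonical, steps = standardize(smi, config)
        records.append(MoleculeRecord(id=rid, input_smiles=smi, canonical_smiles=canonical,
                                      status="ok", applied_steps=["screen", *steps]))

    records = deduplicate(records)
    counts = Counter(r.status for r in records)
    logger.info("curation counts: %s", dict(counts))
    surviving = [i for i, r in enumerate(records) if r.status == "ok"]
    if not surviving:
        raise ValueError("no compounds survived curation")
    return records, raw.activities.take_rows(surviving)
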