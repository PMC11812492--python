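"""Desk-scale synthetic kinase-panel-like datasets for end-to-end testing.

Compounds are built by decorating a handful of template cores (benzene,
pyridine, indole-like, piperazine) with small curation-safe substituents, so
scaffold clusters genuinely exist in fingerprint space. Per-target pKI
values are drawn scaffold-wise from cluster-correlated Gaussians, one
designated "promiscuous" scaffold being active across most targets; a
per-cell missing mask emulates the incomplete annotation of real panels.
Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np

from chemmultiverse.dataio import ActivityMatrix, RawDataset

#: (name, template with two substitution sites). Sites take a substituent
#: each; unordered pairs are enumerated so symmetric cores cannot emit the
#: same molecule twice.
SCAFFOLD_TEMPLATES = (
    ("benzene", "c1cc({0})ccc1{1}"),
    ("pyridine", "c1cc({0})cnc1{1}"),
    ("indole", "Cc1cc2cc({0})ccc2n1{1}"),
    ("piperazine", "O=C({0})N1CCN(CC1)C(=O){1}"),
)

#: Curation-safe substituents (halogens, methyl, methoxy, amino, hydroxy,
#: carboxyl and small alkyls) — none triggers normalization or fragment loss.
SUBSTITUENTS = ("F", "Cl", "Br", "I", "C", "CC", "OC", "N", "O")

PKI_RANGE = (3.0, 10.0)
WITHIN_SCAFFOLD_SD = 0.4


@dataclass
class SynthConfig:
    """Generation parameters; defaults give the 60 x 5 fixture panel."""

    n_compounds: int = 60
    n_targets: int = 5
    n_scaffolds: int = 3
    missing_fraction: float = 0.2
    active_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_scaffolds <= self.n_compounds:
            raise ValueError("need n_compounds >= n_scaffolds >= 1")
        if self.n_scaffolds > len(SCAFFOLD_TEMPLATES):
            raise ValueError(f"at most {len(SCAFFOLD_TEMPLATES)} scaffolds available")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if not 0 <= self.active_fraction <= 1:
            raise ValueError("active_fraction must be in [0, 1]")
        if self.n_targets < 1:
            raise ValueError("need at least one target")


def scaffold_assignment(config: SynthConfig) -> np.ndarray:
    """Scaffold index of each compound (round-robin, deterministic)."""
    return np.arange(config.n_compounds) % config.n_scaffolds


def _enumerate_smiles(config: SynthConfig, rng: np.random.Generator) -> list[str]:
    pairs = list(combinations_with_replacement(SUBSTITUENTS, 2))
    per_scaffold = [int(np.sum(scaffold_assignment(config) == s))
                    for s in range(config.n_scaffolds)]
    if max(per_scaffold) > len(pairs):
        raise ValueError(
            f"requested {max(per_scaffold)} compounds on one scaffold but the "
            f"decoration space holds only {len(pairs)}"
        )
    smiles_by_scaffold = []
    for s in range(config.n_scaffolds):
        template = SCAFFOLD_TEMPLATES[s][1]
        order = rng.permutation(len(pairs))[: per_scaffold[s]]
        smiles_by_scaffold.append([template.format(*pairs[i]) for i in order])
    out, cursors = [], [0] * config.n_scaffolds
    for s in scaffold_assignment(config):
        out.append(smiles_by_scaffold[s][cursors[s]])
        cursors[s] += 1
    return out


def generate(config: SynthConfig | None = None) -> RawDataset:
    """Generate a reproducible scaffold-clustered dataset with pKI panel.

    Scaffold 0 is the promiscuous one: its per-target baselines sit in the
    active range for every target. Other scaffolds are active on a random
    ``active_fraction`` of targets and inactive-to-nonspecific elsewhere.
    Per-compound values scatter around the scaffold-target baseline with
    SD 0.4 and are clipped to the realistic assay range [3, 10].
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)

    smiles = _enumerate_smiles(config, rng)
    ids = [f"SYN_{i + 1:04d}" for i in range(config.n_compounds)]

    baselines = np.empty((config.n_scaffolds, config.n_targets))
    baselines[0] = rng.normal(7.5, 0.4, config.n_targets)  # promiscuous scaffold
    for s in range(1, config.n_scaffolds):
        active = rng.random(config.n_targets) < config.active_fraction
        baselines[s] = np.where(
            active, rng.normal(7.0, 0.4, config.n_targets),
            rng.normal(4.2, 0.6, config.n_targets),
        )

    assign = scaffold_assignment(config)
    values = baselines[assign] + rng.normal(0.0, WITHIN_SCAFFOLD_SD,
                                            (config.n_compounds, config.n_targets))
    values = np.clip(values, *PKI_RANGE)
    mask = rng.random(values.shape) < config.missing_fraction
    values = np.where(mask, np.nan, values)

    return RawDataset(
        records=list(zip(ids, smiles)),
        activities=ActivityMatrix(
            values=values,
            endpoint_names=[f"kinase_{t + 1}" for t in range(config.n_targets)],
            missing_mask=mask,
        ),
    )
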