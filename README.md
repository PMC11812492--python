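# chemmultiverse

A "chemical multiverse" toolkit for multi-target drug discovery: it takes one
set of compounds (SMILES plus pKI/pIC50 activities against many endpoints,
e.g. a kinase panel) and builds **several** chemical-space views of it at
once, one per descriptor representation, so that structure–multiple-activity
relationships can be read off visually instead of from one arbitrary
projection.

One run performs:

1. **Curation** — MolVS-style SMILES standardization (element screen,
   iterative normalization, neutralization, largest covalent fragment,
   reionization, canonical tautomer, canonical SMILES, duplicate removal).
2. **Descriptors** — MACCS keys (166 bits), ECFP4/ECFP6 (2048 bits,
   radius 2/3), six drug-likeness properties (MW, cLogP, TPSA, HBD, HBA,
   RB), plus pluggable external blocks (e.g. learned bioactivity
   signatures) loaded from CSV.
3. **Similarity** — Tanimoto `|A∩B|/|A∪B|` on fingerprints (distance
   `1 − T`), standardized Euclidean distance on continuous blocks.
4. **Projection** — PCA (with explained-variance fractions) and t-SNE
   (precomputed-distance mode, default perplexity 50, seeded).
5. **Validation** — every 2-D map gets a quality report: Venna–Kaski
   trustworthiness `T(k)` and continuity (rank-based neighborhood
   preservation, both in [0, 1]) and the Pearson correlation between
   original and embedded pairwise distances.
6. **Multi-activity aggregation** — per-compound mpIC50 (mean over observed
   endpoints), activity SD normalized to [0, 1] for point sizing,
   per-endpoint category scores (active pKI ≥ 6 → 4, non-specific
   4.5 ≤ pKI < 6 → 3, inactive < 4.5 → 2, unknown → 1), their sum as an
   aggregate score, and promiscuity fractions (share of observed endpoints
   hit at 1 µM ⇔ pKI ≥ 6 and at 100 nM ⇔ pKI ≥ 7).
7. **Visualization** — one self-contained interactive HTML page per
   (descriptor, method) space: orange→blue color scale (mpIC50 by default),
   SD-based point sizes, hover cards with id, SMILES, drug-likeness values
   and an embedded 2-D structure drawing; plus an index page listing each
   space with its quality metrics. The files work fully offline.

A seeded synthetic generator (`chemmultiverse.synthdata`) builds
kinase-panel-like fixtures — scaffold-clustered compounds with
cluster-correlated pKI values and controlled missingness — so the whole
pipeline is testable without any external download.

## Worked example

```bash
python examples/01_curate_and_score.py
```

prints (abridged):

```
curation statuses:
  asp    ok                 CC(=O)Oc1ccccc1C(=O)O
  caf    ok                 Cn1c(=O)c2c(ncn2C)n(C)c1=O
  asp2   duplicate_removed
  metal  disallowed_element
  pot    ok                 Cc1ccc2nc(N)sc2c1

 id  mpic50    sd  sd_norm  aggregate_score  frac_1uM  frac_100nM
asp   6.650 0.778      1.0                9       1.0         0.5
caf   5.133 0.321      0.2                9       0.0         0.0
pot   7.800 0.265      0.1               12       1.0         1.0
```

`asp2` is the same molecule as `asp` spelled differently, so it is removed
as a duplicate; the organolead compound fails the element screen. `asp`
averages pKI 6.65 over its two measured endpoints, hits both at 1 µM but
only one at 100 nM, and its aggregate score 9 = 4 + 4 + 1 (two actives plus
one unknown endpoint). `pot` is active everywhere (score 12, both
promiscuity fractions 1.0).

`examples/02_project_and_validate.py` embeds the 60-compound synthetic panel
from ECFP4 Tanimoto distances and prints, e.g.

```
pca   trustworthiness=0.823 continuity=0.901 correlation=0.590
tsne  trustworthiness=0.946 continuity=0.930 correlation=0.634
```

— t-SNE preserves local fingerprint neighborhoods better than a 2-component
PCA of the sparse bit matrix, which is the typical pattern on clustered
structural data. `examples/03_render_multiverse.py` runs the full pipeline
and writes the browsable HTML multiverse to `scratch/multiverse_demo/`.

The same pipeline is available from the shell:

```bash
chemmultiverse fixtures --out panel.csv --seed 7
chemmultiverse run --input panel.csv --out out/ \
    --descriptors ecfp4,druglikeness --methods pca,tsne --seed 42
```

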