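# Methods

## Curation model

Standardization follows the MolVS protocol as implemented in RDKit's
`rdMolStandardize`, in this fixed order: iterative normalization of
functional-group/charge-separation SMARTS (to a fixpoint, capped at
`max_normalization_iterations = 200`, warning on cap), neutralization,
largest-covalent-fragment selection, reionization, canonical tautomer
selection (on by default; switchable because it dominates runtime on large
sets), canonical SMILES writing. The map is idempotent and invariant to the
input SMILES spelling, which the test suite checks on randomized atom
orderings.

The uncharger runs with `force=True` so a charged species is neutralized
even when a counterion is still present — without this, RDKit preserves
overall charge balance and a sodium carboxylate would come out of the
pipeline as the anion because the salt is only removed one step later.

The element screen precedes standardization and uses the drug-like superset
{H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}. A consequence users should
know: compounds supplied as alkali-metal salts are rejected at the screen
(the counterion is still attached at that point). Supply desalted input or
extend `allowed_elements`. Unparseable SMILES are reported as a distinct
status (`unparseable`) rather than as element rejections.

Duplicates (identical canonical SMILES) keep the first occurrence; the
activity rows of removed duplicates are dropped and logged, not averaged —
merging assay values across records with unknown provenance is a judgment
call we leave to the user upstream.

## Descriptor spaces

* MACCS: RDKit's 167-bit vector has an unused bit 0; we drop it so key *k*
  maps to column *k −1*, width exactly 166.
* ECFP4/ECFP6: Morgan fingerprints at radius 2/3 (diameter 4/6 — both
  namings occur in the literature), folded to 2048 count-insensitive bits.
* Drug-likeness: MW, Crippen cLogP (atom-contribution model), TPSA, HBD,
  HBA, and rotatable bonds under the strict definition (non-ring single
  bonds between non-terminal heavy atoms, amide C–N excluded), in that
  fixed column order.
* External blocks: any n × d numeric CSV keyed by compound id enters the
  continuous path unchanged; this is the hook for learned bioactivity
  signatures, which this package deliberately does not compute.

## Distances and projections

Fingerprint blocks use Tanimoto similarity; the 0/0 case (two all-zero
vectors) is defined as similarity 0.0 with a warning — claiming identity of
two molecules with no detected features would be worse than claiming
dissimilarity. Continuous blocks are z-standardized per column (zero-variance
columns dropped with a warning) before Euclidean distance and before PCA;
without this, MW dominates every other property by two orders of magnitude.

PCA keeps the first two components and reports explained-variance
fractions. Binary matrices are mean-centered but not scaled: unit-variance
scaling of rare bits amplifies noise. t-SNE runs in precomputed-distance
mode for fingerprint spaces and on the standardized vectors for continuous
spaces; default perplexity 50, guarded by perplexity < (n−1)/3, which the
orchestrated pipeline auto-lowers (with a warning) for small sets where the
default is impossible. The seed is explicit everywhere; a fixed seed gives
bit-identical coordinates on the same machine, while across platforms only
the quality metrics are comparable.

## Embedding quality

Trustworthiness is the Venna–Kaski statistic
T(k) = 1 − 2/(n·k·(2n−3k−1)) · Σᵢ Σ_{j∈Uᵢ(k)} (r(i,j) − k), where Uᵢ(k) are
the points in i's k-nearest-neighborhood in the embedding but not in the
original space and r(i,j) is j's 1-based rank among i's original-space
neighbors. Continuity is the same statistic with the two spaces swapped.
Distance ties are broken by point index (stable sort) for reproducibility.
Correlation is Pearson on the upper-triangle distance pairs by default;
Spearman is available via a flag since "correlation" is genuinely ambiguous
in this context. k defaults to 5, the common choice in the
embedding-quality literature; none of these three choices has a canonical
value dictated by the method itself, so all are configurable and recorded
in the per-space quality report.

## Multi-activity aggregation

All activities are pKI/pIC50 (−log₁₀ molar), so 1 µM ⇔ 6 and 100 nM ⇔ 7.
mpIC50 is the arithmetic mean over observed endpoints only and is undefined
(not zero) for a compound with no data. SD uses the sample (n−1)
denominator and needs ≥ 2 observed values. Point sizes min–max normalize
the SDs to [0, 1] and then map affinely onto [min_size, 1]; undefined SDs,
and all SDs when the set is degenerate (all equal), get `min_size`, keeping
no-variability compounds visible but small. Category scores are
active ≥ 6 → 4, non-specific [4.5, 6) → 3, inactive < 4.5 → 2, unknown → 1
(thresholds configurable); the aggregate score is their sum, bounded by
[m, 4m] over m endpoints. Promiscuity is reported as the two per-compound
fractions of observed endpoints hit at pKI ≥ 6 and ≥ 7 — the 100 nM
fraction can never exceed the 1 µM one.

## Visualization

Pages are hand-rendered self-contained HTML: an inline SVG scatter, a small
vanilla-JS tooltip layer and base64-embedded RDKit SVG depictions
(250 × 200), so a rendered multiverse can be archived or e-mailed and
browsed with no network and no JavaScript dependencies. The default
continuous palette runs orange (low) → blue (high); any matplotlib palette
name or explicit color list is accepted. Color position is a monotone
min–max map of the colored value; compounds with no activity data draw
gray at minimum size so the "unknown" class stays visible. Rendering embeds
no timestamps: identical inputs give byte-identical files.

## Synthetic panels

The generator emulates a kinase-profiling matrix at desk scale: compounds
are decorations of up to four template cores (benzene, pyridine,
indole-like, piperazine diamide) with nine curation-safe substituents,
enumerated as unordered pairs so symmetric cores cannot emit one molecule
twice; per-target pKI values are scaffold-correlated Gaussians (within-
scaffold SD 0.4, clipped to the realistic assay range [3, 10]), scaffold 0
being promiscuous (active baselines on every target) while other scaffolds
are active on an `active_fraction` of targets; missingness is i.i.d.
Bernoulli per cell. Defaults are 60 compounds × 5 targets × 3 scaffolds
with 20 % missingness — large enough for t-SNE and the neighborhood metrics
to be meaningful, small enough for the whole pipeline to run in seconds.

What the fixture does **not** emulate: real assay noise structure
(missingness in panels is not random — weak binders go unmeasured),
activity cliffs, stereochemistry, tautomer-rich chemotypes, and any real
selectivity profile. Passing tests on it demonstrate the pipeline's
correctness contracts (alignment, determinism, metric math, scaffold
clustering), not predictive validity on real panels.

## Numerical and scale choices

Distance matrices are dense (the intended working range is up to a few
tens of thousands of compounds); the acceptance script and test suite use
the 60 × 5 default panel with perplexity 15 so a full run including two
t-SNE fits takes seconds. Tanimoto ties, PCA sign indeterminacy (tests
compare up to sign) and t-SNE's platform-dependent coordinates are all
treated as documented non-determinism boundaries; everything else is exact
under a fixed seed.
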