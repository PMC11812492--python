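"""Project one descriptor space to 2-D and validate the embedding.

Generates the 60-compound synthetic kinase panel, computes ECFP4
fingerprints, embeds the Tanimoto-distance matrix with PCA and t-SNE, and
reports trustworthiness / continuity / distance correlation for each.
Higher trustworthiness and continuity (max 1.0) mean the 2-D neighborhoods
faithfully reflect the fingerprint-space neighborhoods.
"""

from chemmultiverse import (
    compute_block,
    curate_dataset,
    evaluate_embedding,
    pairwise_distance,
    pca_project,
    tsne_project,
)
from chemmultiverse.synthdata import SynthConfig, generate

dataset = generate(SynthConfig(n_compounds=60, n_targets=5, n_scaffolds=3, seed=7))
records, activities = curate_dataset(dataset)
smiles = [r.canonical_smiles for r in records if r.status == "ok"]

block = compute_block(smiles, "ecfp4")
dist = pairwise_distance(block)
print(f"ECFP4 block: {block.n} compounds x {block.d} bits")

pca = pca_project(block)
print(f"\nPCA explained variance: PC1 {pca.explained_variance[0]:.1%}, "
      f"PC2 {pca.explained_variance[1]:.1%}")
for name, emb in [("pca", pca), ("tsne", tsne_project(dist, perplexity=15, seed=42))]:
    rep = evaluate_embedding(dist, emb, k=5)
    print(f"{name:5s} trustworthiness={rep.trustworthiness:.3f} "
          f"continuity={rep.continuity:.3f} correlation={rep.correlation:.3f}")
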