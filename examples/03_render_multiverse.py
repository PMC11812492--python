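"""Run the whole pipeline and render the interactive chemical multiverse.

Writes every artifact of one reproducible run — curation report, descriptor
matrices, 2-D coordinates, quality metrics, activity summary and one
self-contained HTML page per (descriptor, method) space plus an index — to
scratch/multiverse_demo/. Open index.html in any browser (offline is fine);
hovering a point shows the compound id, SMILES, drug-likeness properties and
its 2-D structure.
"""

import json
import tempfile
from pathlib import Path

from chemmultiverse.cli import RunConfig, run
from chemmultiverse.dataio import write_table
from chemmultiverse.synthdata import SynthConfig, generate

out = Path("scratch/multiverse_demo")
out.mkdir(parents=True, exist_ok=True)

with tempfile.TemporaryDirectory() as tmp:
    csv = Path(tmp) / "panel.csv"
    write_table(generate(SynthConfig(n_compounds=60, n_targets=5, seed=7)), csv)
    manifest = run(RunConfig(input=str(csv), out=str(out),
                             descriptors=["ecfp4", "druglikeness"],
                             methods=["pca", "tsne"],
                             perplexity=15, seed=42, k=5))

print(json.dumps(manifest, indent=2))
print(f"\nopen {out / 'index.html'} to browse the spaces")
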