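"""Curate a small compound table and compute multi-activity aggregates.

Builds a five-compound input containing a duplicate SMILES spelling and a
disallowed-element entry, runs the standardization pipeline, then scores the
survivors against three endpoints. Note that the element screen runs before
salt stripping, so a compound supplied as e.g. a sodium salt must either
have Na added to ``allowed_elements`` or be supplied desalted.
"""

import numpy as np

from chemmultiverse import curate_dataset, summarize_activities
from chemmultiverse.dataio import ActivityMatrix, RawDataset

values = np.array([
    [7.2, 6.1, np.nan],   # aspirin: active on two kinases, untested on one
    [5.0, 4.9, 5.5],      # caffeine-like: non-specific everywhere
    [7.2, 6.1, np.nan],   # aspirin again, spelled differently -> duplicate
    [np.nan, np.nan, np.nan],
    [8.0, 7.5, 7.9],
])
raw = RawDataset(
    records=[
        ("asp", "CC(=O)Oc1ccccc1C(=O)O"),           # aspirin
        ("caf", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
        ("asp2", "OC(=O)c1ccccc1OC(C)=O"),           # same molecule as "asp"
        ("metal", "CC[Pb](CC)(CC)CC"),               # organolead: rejected
        ("pot", "Cc1ccc2nc(N)sc2c1"),
    ],
    activities=ActivityMatrix(values=values,
                              endpoint_names=["KIN_A", "KIN_B", "KIN_C"],
                              missing_mask=np.isnan(values)),
)

records, activities = curate_dataset(raw)
print("curation statuses:")
for r in records:
    print(f"  {r.id:6s} {r.status:18s} {r.canonical_smiles or ''}")

ok_ids = [r.id for r in records if r.status == "ok"]
summary = summarize_activities(ok_ids, activities)
print("\nactivity summary (mpic50 = mean pKI over observed endpoints;")
print("aggregate_score sums per-endpoint categories 4/3/2/1;")
print("frac_1uM / frac_100nM = share of observed endpoints hit at pKI >= 6 / >= 7):")
print(summary[["id", "mpic50", "sd", "sd_norm", "aggregate_score",
               "frac_1uM", "frac_100nM"]].round(3).to_string(index=False))
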