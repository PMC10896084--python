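"""Negative-control decontamination and frequency-of-occurrence tables.

A simulated multi-marker eDNA survey carries contaminant ESVs that appear
in the extraction blanks; anything seen in a batch's negative control is
struck from that batch's samples before taxa are tabulated.
"""

import pandas as pd

import detritrace as dt
from detritrace import community, taxonomy

scenario = dt.EdnaScenario(dropout=0.05, contamination_rate=0.2)
ds = dt.generate_edna_dataset(scenario, seed=11)

meta = ds.metadata
negatives = list(meta.loc[meta["is_negative"], "sample_id"])
batches = dict(zip(meta["sample_id"], meta["batch"]))

assignments, detections = {}, {}
for marker in scenario.markers:
    cleaned, log = taxonomy.remove_negative_control_esvs(
        ds.detections[marker], negatives, batches)
    if not log.empty:
        print(f"{marker}: removed {log['samples_affected'].sum()} detections "
              f"of {log['esv_id'].nunique()} blank-borne ESV(s)")
    assignments[marker] = taxonomy.assign_hit_table(ds.hit_tables[marker])
    detections[marker] = cleaned

table = taxonomy.consolidate_markers(assignments, detections)
table = taxonomy.apply_taxon_blocklist(table)

real = meta.loc[~meta["is_negative"]]
freq = community.frequency_table(table, real, rank="phylum")
print()
print(freq.to_string(index=False))
print("\nEach cell is the percent of that sample type's samples in which")
print("the phylum was detected by any marker after decontamination.")
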