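"""Rank-thresholded taxonomic assignment from a BLAST-style hit table.

The similarity score is percent identity x percent query coverage; each
rank has a minimum score (phylum 85, class/order 90, family 95, genus 98,
species 99). A hit scoring 96 identifies its family but not its genus,
and a tie between two names leaves the rank undefined.
"""

import pandas as pd

import detritrace as dt

lineage = ("Porifera", "Demospongiae", "Chondrillida", "Halisarcidae",
           "Halisarca", "Halisarca caerulea")
hits = pd.DataFrame([
    {"esv_id": "esv1", "marker": "COI",
     **dict(zip(dt.RANKS, lineage)),
     "pct_identity": 96.0, "pct_coverage": 100.0, "evalue": 1e-30},
])

a = dt.assign_ranks(hits)
print(f"score = {dt.similarity_score(96.0, 100.0)}")
for rank in dt.RANKS:
    print(f"{rank:>8}: {a.assigned[rank] or '(undefined)'}"
          f"   best score {a.best_score[rank]}")
print("\nThe 96-scoring hit clears every bar through family (95) but not")
print("genus (98), so assignment stops at Halisarcidae.")
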