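"""Cluster CDR loop conformations and classify apo-to-holo shifts.

Generates three planted loop families (two with rich sequence
diversity, one with only two unique sequences), computes anchor-aligned
DTW distances, clusters them with HDBSCAN and labels each cluster
canonical (> 2 unique sequences) or pseudo.  Then classifies a few
apo/holo label transitions into the 11-way shift taxonomy.
"""

from collections import Counter

from tcrmotion import loop_clustering as lc
from tcrmotion import synthetic_data as sd

loops = sd.make_loop_families(k=3, m=8, intra_sigma=0.1, inter_sep=1.0,
                              unique_seqs=[5, 5, 2], seed=11)
matrix = lc.build_distance_matrix(loops)
labels = lc.cluster_loops(matrix, {l.loop_id: l.sequence for l in loops})

print("cluster labels (family -> label):")
by_family = {}
for a in labels:
    by_family.setdefault(a.loop_id.split("_")[0], Counter())[str(a)] += 1
for fam, counts in sorted(by_family.items()):
    print(f"  {fam}: {dict(counts)}")

by_id = {a.loop_id: a for a in labels}
print()
print("example apo -> holo shift classifications:")
for apo_id, holo_id in [("fam0_m0", "fam0_m1"), ("fam0_m0", "fam2_m0"),
                        ("fam2_m0", "fam2_m1")]:
    cat = lc.classify_shift(by_id[apo_id], by_id[holo_id])
    print(f"  {by_id[apo_id]} -> {by_id[holo_id]}: {cat.value}")
print()
print("All three families are recovered; the low-diversity family is a")
print("pseudo cluster, and label transitions map onto the shift taxonomy.")
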