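"""Run the whole pipeline: simulate -> curate -> ... -> report.

Generates a synthetic study (holo complexes plus perturbed apo TCRs and
apo pMHCs with planted motions), writes everything as PDB/CSV, then
runs every analysis stage and prints the key numbers of the final
statistical report.
"""

import json
import tempfile
from pathlib import Path

from tcrmotion import cli

out = Path(tempfile.mkdtemp(prefix="tcrmotion_demo_"))
print(f"working directory: {out}")

cli.run_simulate(out, seed=1, n_entities=6)
cli.run_curate(out)
cli.run_movement(out)
cli.run_deformation(out)
cli.run_cluster(out)
cli.run_contacts(out)
cli.run_anchors(out)
report = cli.run_report(out, seed=1)

print(f"\nrecords: {report['n_records']}, matched apo/holo pairs: {report['n_pairs']}")
print("\nmean apo:holo backbone RMSD per loop (A):")
for loop, mean in report["loop_movement_means"].items():
    print(f"  {loop}: {mean:.3f}")
kw = report["loop_movement_kruskal"]
print(f"Kruskal-Wallis across loops: H = {kw['H']:.2f}, p = {kw['p']:.2e}")
print("\npMHC region movement (A):")
for region, mean in report["pmhc_region_means"].items():
    print(f"  {region}: {mean:.3f}")
print(f"\ndual-mode TCR loops (both < 0.5 A and > 1.0 A seen): "
      f"{report['n_dual_mode']}")
print("\nArtifacts (movement.csv, cluster_shift_counts.csv, fingerprint_*.csv,")
print("anchor_profiles.csv, report.json) are left in the directory above.")
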