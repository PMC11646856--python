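"""Distinguish internal loop deformation from bulk movement.

Plants a mid-peak internal deformation (maximal at the loop centre,
zero at the flanks) on a CDR3a loop and shows that the loop-superposed
backbone RMSD equals the closed-form expected value, with the
per-residue profile peaking mid-loop — the shape characteristic of a
plastically deforming loop.
"""

from tcrmotion import superposition as sp
from tcrmotion import synthetic_data as sd

base = sd.make_toy_tcr(seed=3)
spec = sd.PerturbationSpec("CDR3a", internal_amplitude=1.0, profile="midpeak", seed=4)
apo, holo, truth = sd.make_apo_holo_pair(base, spec)

aligned, _ = sp.align_tcr_framework(apo, holo)
loop_apo = sp.loop_residues(aligned, "CDR3a")
loop_holo = sp.loop_residues(holo, "CDR3a")

measured = sp.backbone_rmsd(loop_apo, loop_holo, superpose_first=True)
print(f"loop-superposed RMSD: {measured:.6f} A "
      f"(closed-form expectation {truth.expected_superposed_rmsd:.6f} A)")
print()
print("per-residue heavy-atom RMSD profile (IMGT position: movement):")
for key, value in sorted(truth.expected_per_residue.items()):
    bar = "#" * int(round(40 * value / max(truth.expected_per_residue.values())))
    print(f"  {key[0]:>4}  {value:.3f} A  {bar}")
print()
print("The profile is maximal mid-loop and vanishes toward the flanks: the")
print("loop changes shape internally rather than swinging as a rigid body.")
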