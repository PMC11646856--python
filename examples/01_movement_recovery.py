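"""Measure CDR loop movement between apo and holo TCR states.

Builds a toy TCR, plants a known 2.0 Å rigid displacement of its CDR3b
loop to create an apo form, aligns apo onto holo on the framework
regions and measures the loop's backbone RMSD — once in the framework
frame (bulk movement) and once after superposing the loop itself
(internal deformation only).
"""

from tcrmotion import superposition as sp
from tcrmotion import synthetic_data as sd

base = sd.make_toy_tcr(seed=1)
spec = sd.PerturbationSpec("CDR3b", rigid_displacement=2.0, seed=2)
apo, holo, truth = sd.make_apo_holo_pair(base, spec)

aligned, fit = sp.align_tcr_framework(apo, holo)
loop_apo = sp.loop_residues(aligned, "CDR3b")
loop_holo = sp.loop_residues(holo, "CDR3b")

print(f"framework fit RMSD:        {fit.fit_rmsd:.2e} A  ({fit.n_atoms} atoms)")
print(f"CDR3b backbone RMSD:       {sp.backbone_rmsd(loop_apo, loop_holo):.6f} A"
      f"  (planted {truth.expected_unsuperposed_rmsd:.6f} A)")
print(f"CDR3b loop-superposed RMSD: "
      f"{sp.backbone_rmsd(loop_apo, loop_holo, superpose_first=True):.2e} A")
print()
print("The framework fit is exact (the framework never moved), the loop RMSD")
print("recovers the planted displacement, and superposing the loop first")
print("removes the rigid motion entirely: the loop moved but did not deform.")
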